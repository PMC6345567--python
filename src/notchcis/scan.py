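"""Latin-Hypercube parameter scans and non-monotonic dose-response analysis.

Each model is probed with an ensemble of kinetic parameter sets drawn by
Latin Hypercube Sampling over four decades ([1e-2, 1e2], stratified on the
log10 scale by default).  For every set, the steady-state level of the
activating cis-complex C+ is computed on a 10-point Delta production-rate
(alpha_D) grid log-spanning a 100-fold range centered on the sampled
Notch production rate alpha_N.  A profile is called non-monotonic when its
first C+ maximum falls strictly inside the grid (between the 2nd and the
(n-2)th point): C+ rises with ligand at low ligand levels (cis-activation)
and falls again at high levels (cis-inhibition).

The fractional incline (C_max - C_first)/C_max and decline
(C_max - C_last)/C_max quantify how strongly a profile rises and then
attenuates, both normalized by the profile maximum so they live on a
common [0, 1] scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .models import (
    MODEL_IDS,
    ParameterSet,
    scanned_parameters,
    solve_steady_state,
)

__all__ = [
    "ScanConfig",
    "ResponseProfile",
    "sample_parameters",
    "alpha_d_grid",
    "profile_features",
    "classify_nonmonotonic",
    "response_profile",
    "scan",
]

_MODEL_INDEX = {m: i for i, m in enumerate(MODEL_IDS)}


@dataclass(frozen=True)
class ScanConfig:
    """Ensemble scan configuration.

    ``param_range`` is the closed sampling interval as log10 exponents;
    ``sampling_scale`` chooses whether LHS strata are equal-width in log10
    (default) or in linear units over the same interval.  ``alpha_d_span``
    is the total fold-range of the dose grid around alpha_N.
    """

    n_sets: int = 10_000
    param_range: tuple[float, float] = (-2.0, 2.0)
    n_alpha_d: int = 10
    alpha_d_span: float = 100.0
    seed: int = 0
    model_ids: tuple[str, ...] = ("M0", "M1", "M2a", "M2b", "M2c", "M2d")
    sampling_scale: str = "log"
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.n_alpha_d < 3:
            raise ValueError("n_alpha_d must be >= 3")
        if not self.alpha_d_span > 1:
            raise ValueError("alpha_d_span must exceed 1")
        if self.sampling_scale not in ("log", "linear"):
            raise ValueError("sampling_scale must be 'log' or 'linear'")
        for m in self.model_ids:
            if m not in _MODEL_INDEX:
                raise ValueError(f"unknown model id {m!r}")


@dataclass
class ResponseProfile:
    """Steady-state C+ along the alpha_D dose grid, with shape features."""

    alpha_d_grid: np.ndarray
    c_plus: np.ndarray
    free_d: np.ndarray
    peak_index: int  # 1-based, first index attaining the maximum
    incline: float
    decline: float
    nonmonotonic: bool
    n_converged: int

    @property
    def all_converged(self) -> bool:
        return self.n_converged == len(self.alpha_d_grid)


def _model_rng(config: ScanConfig, model: str) -> np.random.Generator:
    # Per-model substream keyed on the canonical model index, so extending
    # the model list never perturbs another model's draws.
    ss = np.random.SeedSequence(
        entropy=int(config.seed), spawn_key=(_MODEL_INDEX[model],)
    )
    return np.random.default_rng(ss)


def sample_parameters(config: ScanConfig,
                      model: str = "M2c") -> list[ParameterSet]:
    """Draw ``config.n_sets`` Latin-Hypercube parameter sets for ``model``.

    Every scanned dimension is stratified with exactly one draw per
    equal-width bin on the sampling scale.  alpha_D is left at 1; the dose
    grid overrides it downstream.
    """
    names = scanned_parameters(model)
    sampler = qmc.LatinHypercube(d=len(names), seed=_model_rng(config, model))
    unit = sampler.random(config.n_sets)
    lo, hi = config.param_range
    if config.sampling_scale == "log":
        values = 10.0 ** (lo + (hi - lo) * unit)
    else:
        a, b = 10.0 ** lo, 10.0 ** hi
        values = a + (b - a) * unit
    return [
        ParameterSet(**dict(zip(names, row))) for row in values
    ]


def alpha_d_grid(alpha_N: float, config: ScanConfig) -> np.ndarray:
    """Log-equispaced alpha_D doses spanning ``alpha_d_span``-fold around
    ``alpha_N`` (symmetric in log, so span 100 gives alpha_N * 10**±1)."""
    if not alpha_N > 0:
        raise ValueError("alpha_N must be positive")
    half = np.sqrt(config.alpha_d_span)
    return np.geomspace(alpha_N / half, alpha_N * half, config.n_alpha_d)


def profile_features(c_plus: Sequence[float]) -> tuple[int, float, float]:
    """(peak_index, incline, decline) of a C+ dose profile.

    peak_index is 1-based and takes the first of tied maxima, so flat
    profiles report peak_index 1 and classify as monotonic.  Incline and
    decline are the fractional rise from the first grid point and drop to
    the last, both relative to the profile maximum and clamped to [0, 1].
    An all-zero (or degenerate non-positive) profile reports (1, 0, 0).
    """
    c = np.asarray(c_plus, dtype=float)
    if c.size < 3:
        raise ValueError("need at least 3 profile values")
    cmax = float(np.max(c))
    if not cmax > 0:
        return 1, 0.0, 0.0
    peak = int(np.argmax(c)) + 1
    incline = float(np.clip((cmax - c[0]) / cmax, 0.0, 1.0))
    decline = float(np.clip((cmax - c[-1]) / cmax, 0.0, 1.0))
    return peak, incline, decline


def classify_nonmonotonic(peak_index: int, n_alpha_d: int) -> bool:
    """True when the first C+ maximum lies strictly inside the dose grid
    (positions 2 .. n-2 inclusive; for the default 10-point grid, 2..8)."""
    return 2 <= peak_index <= n_alpha_d - 2


def response_profile(model: str, params: ParameterSet,
                     grid: Sequence[float],
                     tol: float = 1e-10) -> ResponseProfile:
    """Steady-state C+ response of ``params`` along an alpha_D grid.

    Profiles with any non-converged grid point get NaN features and are
    never classified non-monotonic; callers exclude them from ensemble
    fractions via ``all_converged``.
    """
    grid = np.asarray(grid, dtype=float)
    c_plus = np.full(grid.size, np.nan)
    free_d = np.full(grid.size, np.nan)
    for i, a_d in enumerate(grid):
        ss = solve_steady_state(model, params.replace(alpha_D=float(a_d)),
                                tol=tol)
        if ss.converged:
            c_plus[i] = ss.c_plus
            free_d[i] = ss.free_d
    n_conv = int(np.sum(np.isfinite(c_plus)))
    if n_conv == grid.size:
        peak, incline, decline = profile_features(c_plus)
        nonmono = classify_nonmonotonic(peak, grid.size)
    else:
        peak, incline, decline, nonmono = 0, np.nan, np.nan, False
    return ResponseProfile(grid, c_plus, free_d, peak, incline, decline,
                           nonmono, n_conv)


def scan(config: ScanConfig,
         models: Iterable[str] | None = None,
         progress: bool = False) -> tuple[dict[str, pd.DataFrame],
                                          pd.DataFrame]:
    """Run the ensemble scan and return (per-model tables, summary).

    Per-model tables carry one row per parameter set (sampled parameters
    plus peak_index/incline/decline/nonmonotonic/n_converged); the summary
    reports the non-monotonic fraction among fully converged profiles.
    """
    models = list(config.model_ids if models is None else models)
    tables: dict[str, pd.DataFrame] = {}
    summary_rows = []
    for model in models:
        psets = sample_parameters(config, model)
        iterator = psets
        if progress:
            from tqdm import tqdm
            iterator = tqdm(psets, desc=f"scan {model}")
        rows = []
        for set_id, p in enumerate(iterator):
            grid = alpha_d_grid(p.alpha_N, config)
            prof = response_profile(model, p, grid, tol=config.tol)
            row: dict[str, float] = {"set_id": set_id}
            row.update({k: getattr(p, k) for k in scanned_parameters(model)})
            row.update(
                peak_index=prof.peak_index,
                incline=prof.incline,
                decline=prof.decline,
                nonmonotonic=prof.nonmonotonic,
                n_converged=prof.n_converged,
            )
            rows.append(row)
        df = pd.DataFrame(rows)
        tables[model] = df
        conv = df["n_converged"] == config.n_alpha_d
        n_conv = int(conv.sum())
        frac = float(df.loc[conv, "nonmonotonic"].mean()) if n_conv else np.nan
        summary_rows.append({
            "model_id": model,
            "n_sets": config.n_sets,
            "n_converged": n_conv,
            "fraction_nonmonotonic": frac,
        })
    return tables, pd.DataFrame(summary_rows)
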