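"""Synthetic single-cell lineage traces and fixture parameter sets.

The generator emulates the measurable features of nuclear H2B-reporter
time-lapse data that the trace pipeline assumes: fluorescence accumulates
as cumulative production (the stable H2B pool is not degraded on the
experiment's timescale), cell divisions split the pool between daughters
with a near-symmetric fraction, and measurement adds white Gaussian noise
on top of background subtraction.  Ground truth (true rate profile,
cumulative curve, and pre-division peak rate) is emitted alongside, so
recovery by the analysis pipeline can be tested quantitatively.

``generate_reporter_traces_from_model`` bridges the steady-state models
to trace space: a cell's production rate is a gain times its steady-state
activating-complex level, mimicking a reporter driven by released
intracellular domain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .models import ParameterSet, SteadyState, solve_steady_state, total_activation
from .traces import CellTrace

__all__ = [
    "TraceSimConfig",
    "LineageGroundTruth",
    "generate_lineage_traces",
    "generate_reporter_traces_from_model",
    "fixture_parameter_sets",
]


@dataclass(frozen=True)
class TraceSimConfig:
    """Synthetic lineage-trace configuration.

    Defaults emulate the study conditions of the time-lapse assay:
    frames every 30 min over 24 h, reporter onset a few frames in, one
    division near frame 24 (a ~12 h cell cycle), a near-even
    Beta(50, 50) division split, and additive measurement noise small
    relative to per-frame accumulation.
    """

    n_cells: int = 20
    n_frames: int = 48
    frame_interval: float = 30.0  # minutes
    onset_frame: int = 6
    plateau_rate: float = 100.0  # a.u./frame once the reporter turns on
    rate_profile: tuple[tuple[float, ...], ...] | None = None
    division_times: tuple[int, ...] = (24,)
    split_beta: tuple[float, float] = (50.0, 50.0)
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_frames < 2 or self.n_cells < 1:
            raise ValueError("need n_frames >= 2 and n_cells >= 1")
        for d in self.division_times:
            if not 0 < d < self.n_frames:
                raise ValueError("division_times must lie within the trace")
        if self.rate_profile is not None:
            if len(self.rate_profile) != self.n_cells:
                raise ValueError("rate_profile needs one row per cell")
            for row in self.rate_profile:
                if len(row) != self.n_frames:
                    raise ValueError("rate_profile rows must have n_frames "
                                     "entries")


@dataclass
class LineageGroundTruth:
    """True per-frame rates/cumulative curves and per-cell summaries."""

    per_frame: pd.DataFrame  # cell_id, frame, true_rate, true_cumulative
    per_cell: pd.DataFrame   # cell_id, true_peak_rate,
    #                          first_division_frame, distance_um


def _default_rates(config: TraceSimConfig) -> np.ndarray:
    rates = np.zeros((config.n_cells, config.n_frames))
    rates[:, config.onset_frame:] = config.plateau_rate
    return rates


def generate_lineage_traces(
    config: TraceSimConfig,
) -> tuple[list[CellTrace], LineageGroundTruth]:
    """Simulate reporter accumulation traces with division splits.

    At each division frame the accumulated pool (including that frame's
    production) is split: the tracked daughter keeps a Beta-drawn
    fraction and the sister's first-frame value is recorded, exactly as
    the trace pipeline expects.  Noise is added last, to the measured
    trace and to the recorded sister values; with ``noise_sd=0`` tracked
    plus sister values conserve the pre-division pool exactly.
    """
    rng = np.random.default_rng(config.seed)
    rates = (np.asarray(config.rate_profile, dtype=float)
             if config.rate_profile is not None else _default_rates(config))
    times = np.arange(config.n_frames) * config.frame_interval
    a, b = config.split_beta
    traces: list[CellTrace] = []
    pf_rows, pc_rows = [], []
    for c in range(config.n_cells):
        r = rates[c]
        value = np.zeros(config.n_frames)
        sisters = []
        for t in range(1, config.n_frames):
            pool = value[t - 1] + r[t]
            if t in config.division_times:
                frac = rng.beta(a, b)
                value[t] = frac * pool
                sisters.append((1.0 - frac) * pool)
            else:
                value[t] = pool
        measured = value + rng.normal(0.0, config.noise_sd,
                                      config.n_frames) \
            if config.noise_sd > 0 else value.copy()
        div = np.asarray(config.division_times, dtype=int)
        sister_vals = np.asarray(sisters)
        if config.noise_sd > 0 and sister_vals.size:
            sister_vals = sister_vals + rng.normal(0.0, config.noise_sd,
                                                   sister_vals.size)
        # Static positions in a 600x600 um field; neighbor distance drawn
        # independently of rate (the cell-autonomy null).
        xy = np.tile(rng.uniform(0, 600, 2), (config.n_frames, 1))
        cell_id = f"cell{c:03d}"
        traces.append(CellTrace(
            cell_id=cell_id,
            frame_times=times,
            fluorescence=measured,
            division_frames=div,
            sister_first_values=sister_vals,
            position=xy,
        ))
        cum = np.cumsum(r)
        first_div = int(div[0]) if div.size else None
        pre = r[1:first_div] if first_div is not None else r[1:]
        pf_rows.extend(
            {"cell_id": cell_id, "frame": t, "true_rate": r[t],
             "true_cumulative": cum[t]}
            for t in range(config.n_frames)
        )
        pc_rows.append({
            "cell_id": cell_id,
            "true_peak_rate": float(np.max(pre)) if pre.size else 0.0,
            "first_division_frame": first_div,
            "distance_um": float(rng.uniform(20.0, 200.0)),
        })
    truth = LineageGroundTruth(pd.DataFrame(pf_rows), pd.DataFrame(pc_rows))
    return traces, truth


def generate_reporter_traces_from_model(
    model: str,
    params: ParameterSet,
    gain: float,
    config: TraceSimConfig,
    tol: float = 1e-10,
) -> tuple[list[CellTrace], LineageGroundTruth, SteadyState]:
    """Traces whose production rate is gain x steady-state activation.

    Solves ``model`` at ``params``; the resulting activating-complex
    level (C+ plus T) scaled by ``gain`` becomes every cell's plateau
    rate, with the configured onset and divisions.  Raises if the model
    does not converge.
    """
    ss = solve_steady_state(model, params, tol=tol)
    if not ss.converged:
        raise ValueError(f"{model} did not converge at these parameters")
    rate = gain * total_activation(model, ss)
    cfg = TraceSimConfig(**{**config.__dict__, "plateau_rate": rate,
                            "rate_profile": None})
    traces, truth = generate_lineage_traces(cfg)
    return traces, truth, ss


def fixture_parameter_sets() -> dict[str, dict[str, object]]:
    """Deterministic fixture library shipped with the package.

    Keys: ``all_ones`` (every rate 1), ``m2c_nonmonotonic`` (a recorded
    scan hit whose cis-only M2c profile is non-monotonic under default
    settings), ``no_binding`` (association rates 0, so C+ stays 0).
    Each entry carries a ``params`` block convertible to
    :class:`ParameterSet` plus provenance notes.
    """
    text = (resources.files("notchcis") / "data" /
            "fixtures.json").read_text()
    return json.loads(text)


def fixture_params(name: str) -> ParameterSet:
    """A fixture entry as a ParameterSet."""
    entry = fixture_parameter_sets()[name]
    return ParameterSet(**entry["params"])
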