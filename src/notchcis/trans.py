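"""Signal integration of cis- and trans-Delta: activation grids and
inhibitory trans dose-responses.

Building on the M2c cis-activation model, these analyses ask what a cell
can read out when Notch sees ligand both on its own membrane (cis-Delta,
set by the production rate alpha_D) and on its neighbors' (a fixed
extracellular level D_trans):

* ``total_activation_grid`` maps total activation (C+ + T) over a
  (trans level x cis alpha_D) grid for the activating-trans model, plus
  the sensitivity of total activation to fold-changes in cis ligand
  (adjacent-column differences along the log-spaced cis axis).
* ``regime_summary`` reduces a grid to median (activation, sensitivity)
  per low/high cis x low/high trans quadrant.
* ``inhibitory_trans_response`` doses the inhibitory-trans model
  (T- sequesters receptor without signaling) at the cis ligand level of
  peak cis-activation.

Trans levels are chosen as the free cis-Delta concentrations the same
parameter set produces without any trans ligand, so the two axes live on
the cell's own concentration scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ParameterSet, solve_steady_state
from .scan import ScanConfig, alpha_d_grid, profile_features, response_profile

__all__ = [
    "ActivationGrid",
    "InhibitoryResponse",
    "choose_trans_levels",
    "total_activation_grid",
    "regime_summary",
    "inhibitory_trans_response",
    "median_inhibitory_curve",
    "find_degenerate_pairs",
]


@dataclass
class ActivationGrid:
    """Total activation C+ + T over (trans level, cis alpha_D).

    ``total_activation[i, j]`` is the steady-state activation at trans
    level i and cis dose j (columns ordered by increasing alpha_D).
    ``sensitivity`` holds adjacent-column differences: column j is
    activation at dose j+1 minus at dose j, i.e. the response to one
    constant fold-change in cis ligand.  Non-converged cells are NaN.
    """

    cis_alpha_d_grid: np.ndarray
    trans_levels: np.ndarray
    total_activation: np.ndarray
    sensitivity: np.ndarray
    params_id: int | str | None = None


@dataclass
class InhibitoryResponse:
    """Total activation vs inhibitory trans-ligand at peak-cis alpha_D."""

    trans_levels: np.ndarray
    activation: np.ndarray
    normalized: np.ndarray  # activation / activation at trans level 0
    peak_alpha_d: float


def choose_trans_levels(params: ParameterSet, cis_grid: np.ndarray,
                        tol: float = 1e-10) -> np.ndarray:
    """Trans-Delta axis: the steady-state free cis-Delta levels the set
    produces at D_trans = 0 across the cis dose grid, sorted ascending.

    Non-converged doses are dropped (with fewer returned levels)."""
    levels = []
    for a_d in np.asarray(cis_grid, dtype=float):
        ss = solve_steady_state(
            "M2c", params.replace(alpha_D=float(a_d), D_trans=0.0), tol=tol
        )
        if ss.converged:
            levels.append(ss.free_d)
    return np.sort(np.asarray(levels))


def total_activation_grid(params: ParameterSet, cis_grid: np.ndarray,
                          trans_levels: np.ndarray,
                          tol: float = 1e-10,
                          params_id: int | str | None = None,
                          ) -> ActivationGrid:
    """Solve the activating-trans model over the full (trans, cis) grid."""
    cis_grid = np.asarray(cis_grid, dtype=float)
    trans_levels = np.asarray(trans_levels, dtype=float)
    total = np.full((trans_levels.size, cis_grid.size), np.nan)
    for i, dt in enumerate(trans_levels):
        for j, a_d in enumerate(cis_grid):
            ss = solve_steady_state(
                "M2c_trans",
                params.replace(alpha_D=float(a_d), D_trans=float(dt)),
                tol=tol,
            )
            if ss.converged:
                total[i, j] = (ss.concentrations["C+"]
                               + ss.concentrations["T"])
    sensitivity = total[:, 1:] - total[:, :-1]
    return ActivationGrid(cis_grid, trans_levels, total, sensitivity,
                          params_id)


def regime_summary(grid: ActivationGrid) -> pd.DataFrame:
    """Median (total activation, sensitivity) per cis/trans regime.

    Both axes are split at their midpoint index into low/high halves;
    the four quadrants are labelled e.g. ``low_cis_high_trans``.  The
    sensitivity matrix has one column fewer than the activation matrix,
    so its own column axis is midpoint-split; with a single sensitivity
    column the low-cis quadrants carry no sensitivity cells (NaN).
    """
    n_trans, n_cis = grid.total_activation.shape
    if n_trans < 2 or n_cis < 2:
        raise ValueError("grid must be at least 2x2 to form quadrants")
    mt, mc = n_trans // 2, n_cis // 2
    ms = (n_cis - 1) // 2
    rows = []
    for trans_regime, t_sl in (("low", slice(0, mt)), ("high", slice(mt, None))):
        for cis_regime, c_sl, s_sl in (
            ("low", slice(0, mc), slice(0, ms)),
            ("high", slice(mc, None), slice(ms, None)),
        ):
            act = grid.total_activation[t_sl, c_sl]
            sens = grid.sensitivity[t_sl, s_sl]
            rows.append({
                "cis_regime": cis_regime,
                "trans_regime": trans_regime,
                "median_total_activation": float(np.nanmedian(act))
                if act.size else np.nan,
                "median_sensitivity": float(np.nanmedian(sens))
                if sens.size and np.any(np.isfinite(sens)) else np.nan,
            })
    return pd.DataFrame(rows)


def inhibitory_trans_response(params: ParameterSet,
                              config: ScanConfig | None = None,
                              trans_levels: np.ndarray | None = None,
                              tol: float = 1e-10) -> InhibitoryResponse:
    """Dose-response of total activation to an inhibitory trans-ligand.

    The cis-Delta production rate is pinned at the dose where the
    cis-only (M2c) profile peaks; the inhibitory-trans model is then
    solved across ``trans_levels`` (defaulting to 0 plus the set's own
    free cis-Delta levels).  Because T- never signals, total activation
    is just C+.  The normalized curve divides by the zero-trans value.
    """
    config = config or ScanConfig()
    grid = alpha_d_grid(params.alpha_N, config)
    prof = response_profile("M2c", params, grid, tol=tol)
    if prof.n_converged == 0:
        raise ValueError("cis-only profile has no converged dose")
    peak_alpha_d = float(grid[np.nanargmax(prof.c_plus)])
    if trans_levels is None:
        levels = prof.free_d[np.isfinite(prof.free_d)]
        trans_levels = np.concatenate(([0.0], np.sort(levels)))
    trans_levels = np.asarray(trans_levels, dtype=float)
    if trans_levels[0] != 0.0:
        trans_levels = np.concatenate(([0.0], trans_levels))
    act = np.full(trans_levels.size, np.nan)
    for i, dt in enumerate(trans_levels):
        ss = solve_steady_state(
            "M2c_trans_inhib",
            params.replace(alpha_D=peak_alpha_d, D_trans=float(dt)),
            tol=tol,
        )
        if ss.converged:
            act[i] = ss.concentrations["C+"]
    normalized = act / act[0] if act[0] and np.isfinite(act[0]) else act * np.nan
    return InhibitoryResponse(trans_levels, act, normalized, peak_alpha_d)


def median_inhibitory_curve(responses: list[InhibitoryResponse]) -> np.ndarray:
    """Per-dose-rank median of normalized inhibitory curves.

    Trans levels differ between parameter sets (each uses its own
    cis-Delta scale), so curves are aligned by dose rank; all curves must
    share the same number of doses."""
    lengths = {r.normalized.size for r in responses}
    if len(lengths) != 1:
        raise ValueError("curves must share the same number of doses")
    stacked = np.vstack([r.normalized for r in responses])
    return np.nanmedian(stacked, axis=0)


def find_degenerate_pairs(grid: ActivationGrid,
                          rtol: float = 0.01) -> list[tuple[tuple[int, int],
                                                            tuple[int, int]]]:
    """Pairs of distinct (trans, cis) cells whose total activation agrees
    within ``rtol`` relative -- combinations a cell cannot tell apart from
    total Notch activity alone."""
    ta = grid.total_activation
    cells = [(i, j) for i in range(ta.shape[0]) for j in range(ta.shape[1])
             if np.isfinite(ta[i, j])]
    pairs = []
    for a in range(len(cells)):
        i, j = cells[a]
        for b in range(a + 1, len(cells)):
            k, l = cells[b]
            if (i, j) == (k, l):
                continue
            hi = max(abs(ta[i, j]), abs(ta[k, l]))
            if hi > 0 and abs(ta[i, j] - ta[k, l]) < rtol * hi:
                pairs.append(((i, j), (k, l)))
    return pairs
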