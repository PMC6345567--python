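"""Time-lapse trace analysis: division correction and production rates.

A nuclear H2B reporter accumulates fluorescence in proportion to
cumulative Notch activity, but every cell division splits the pool
between the two daughters, leaving step discontinuities in single-cell
traces.  ``continuize`` removes them by adding back, from each division
onward, the fluorescence apportioned to the sister cell, recovering the
lineage's cumulative-production curve.  ``production_rate`` then
estimates the per-frame production rate as a smoothed first difference
of the continuized trace, and ``peak_rate`` reports its maximum before
the first division -- the activation readout used for isolated cells.
``neighbor_distance_regression`` tests cell autonomy: a flat slope of
peak rate against distance to the nearest engineered neighbor indicates
a distance-independent (cis) process.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CellTrace",
    "RateTrace",
    "continuize",
    "production_rate",
    "peak_rate",
    "analyze_trace",
    "neighbor_distance_regression",
    "read_traces_csv",
    "write_traces_csv",
]

#: Column order of the long-format trace CSV dialect.
TRACE_COLUMNS = ("cell_id", "frame", "time_min", "fluor", "is_division",
                 "sister_fluor", "x_um", "y_um")


@dataclass
class CellTrace:
    """One cell's background-subtracted fluorescence time series.

    ``division_frames`` lists frame indices t such that a division
    occurred between frames t-1 and t; ``sister_first_values`` aligns to
    it and holds the sister cell's fluorescence at its first
    post-division frame (the amount lost at the split).  Missing frames
    may be NaN; they are linearly interpolated before correction.
    """

    cell_id: str
    frame_times: np.ndarray
    fluorescence: np.ndarray
    division_frames: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int))
    sister_first_values: np.ndarray = field(
        default_factory=lambda: np.array([]))
    position: np.ndarray | None = None  # (n_frames, 2) in um, optional

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.division_frames = np.asarray(self.division_frames, dtype=int)
        self.sister_first_values = np.asarray(self.sister_first_values,
                                              dtype=float)
        n = self.frame_times.size
        if self.fluorescence.size != n:
            raise ValueError("fluorescence and frame_times length mismatch")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        d = self.division_frames
        if d.size and (np.any(np.diff(d) <= 0) or d.min() < 1
                       or d.max() >= n):
            raise ValueError("division_frames must be strictly increasing "
                             "and within (0, n_frames)")

    @property
    def first_division_frame(self) -> int | None:
        return int(self.division_frames[0]) if self.division_frames.size else None


@dataclass
class RateTrace:
    """Division-corrected trace with its derived production-rate series."""

    times: np.ndarray
    continuized: np.ndarray
    production_rate: np.ndarray  # length n-1; entry i is frame i -> i+1
    peak_rate: float
    smoothing_window: int


def _interpolate_missing(values: np.ndarray) -> np.ndarray:
    """Linear interpolation across NaN frames (ends held at nearest)."""
    v = values.astype(float).copy()
    bad = ~np.isfinite(v)
    if not bad.any():
        return v
    if bad.all():
        raise ValueError("trace has no finite fluorescence values")
    idx = np.arange(v.size)
    v[bad] = np.interp(idx[bad], idx[~bad], v[~bad])
    return v


def continuize(trace: CellTrace) -> np.ndarray:
    """Division-corrected ('continuized') fluorescence series.

    From each division frame onward the sister's first post-division
    value is added back, so the pool lost at each split is restored and
    corrections accumulate across successive divisions.  With an exact
    split and no noise the corrected series equals the lineage's
    cumulative production.
    """
    if trace.division_frames.size != trace.sister_first_values.size:
        raise ValueError("every division needs a sister value")
    corrected = _interpolate_missing(trace.fluorescence)
    for d, sister in zip(trace.division_frames, trace.sister_first_values):
        if not np.isfinite(sister):
            raise ValueError(f"missing sister value at division frame {d}")
        corrected[d:] += sister
    return corrected


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with window truncation at the edges."""
    if window == 1:
        return x.astype(float)
    half = window // 2
    c = np.concatenate(([0.0], np.cumsum(x, dtype=float)))
    i = np.arange(x.size)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half + 1, x.size)
    return (c[hi] - c[lo]) / (hi - lo)


def production_rate(continuized: Sequence[float],
                    smoothing_window: int = 3) -> np.ndarray:
    """Smoothed frame-to-frame difference of a continuized trace.

    The trace is smoothed with a centered moving average, differenced
    between consecutive frames, and the difference smoothed again with
    the same window (edges use truncated windows).  Entry i estimates
    the production during frame interval i -> i+1, in a.u./frame.
    """
    x = np.asarray(continuized, dtype=float)
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be odd and >= 1")
    if smoothing_window > x.size:
        raise ValueError("smoothing_window longer than trace")
    smooth = _moving_average(x, smoothing_window)
    diff = np.diff(smooth)
    return _moving_average(diff, smoothing_window)


def peak_rate(rate: Sequence[float],
              first_division_frame: int | None = None) -> float:
    """Maximum production rate over frames strictly before the first
    division (the whole series when the cell never divides)."""
    r = np.asarray(rate, dtype=float)
    if first_division_frame is not None:
        # rate[i] covers frames i -> i+1; keep intervals ending before
        # the division frame.
        r = r[: max(first_division_frame - 1, 0)]
    if r.size == 0:
        raise ValueError("empty pre-division window")
    return float(np.max(r))


def analyze_trace(trace: CellTrace, smoothing_window: int = 3) -> RateTrace:
    """Full per-cell pipeline: continuize, differentiate, take peak."""
    cont = continuize(trace)
    rate = production_rate(cont, smoothing_window)
    return RateTrace(
        times=trace.frame_times,
        continuized=cont,
        production_rate=rate,
        peak_rate=peak_rate(rate, trace.first_division_frame),
        smoothing_window=smoothing_window,
    )


def neighbor_distance_regression(
    peak_rates: Sequence[float],
    distances: Sequence[float],
    ci_level: float = 0.95,
) -> tuple[float, float, tuple[float, float]]:
    """OLS fit of peak rate on neighbor distance with a slope CI.

    Returns (slope, intercept, (ci_low, ci_high)).  A CI covering zero is
    the signature of a distance-independent, cell-autonomous process.
    """
    y = np.asarray(peak_rates, dtype=float)
    x = np.asarray(distances, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("distances are degenerate (zero variance)")
    fit = stats.linregress(x, y)
    stderr = fit.stderr
    if not np.isfinite(stderr):  # zero-variance y: compute from residuals
        resid = y - (fit.slope * x + fit.intercept)
        s2 = float(resid @ resid) / (x.size - 2)
        stderr = np.sqrt(s2 / float(((x - x.mean()) ** 2).sum()))
    tcrit = stats.t.ppf(0.5 + ci_level / 2, x.size - 2)
    ci = (fit.slope - tcrit * stderr, fit.slope + tcrit * stderr)
    return float(fit.slope), float(fit.intercept), (float(ci[0]),
                                                    float(ci[1]))


def read_traces_csv(path: str | Path) -> list[CellTrace]:
    """Read the long-format trace dialect into CellTrace objects."""
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    traces = []
    for cell_id, g in df.groupby("cell_id", sort=False):
        g = g.sort_values("frame")
        div_mask = g["is_division"].astype(bool).to_numpy()
        pos = None
        if {"x_um", "y_um"} <= set(g.columns) and g["x_um"].notna().any():
            pos = g[["x_um", "y_um"]].to_numpy(dtype=float)
        traces.append(CellTrace(
            cell_id=str(cell_id),
            frame_times=g["time_min"].to_numpy(dtype=float),
            fluorescence=g["fluor"].to_numpy(dtype=float),
            division_frames=np.flatnonzero(div_mask),
            sister_first_values=g["sister_fluor"].to_numpy(dtype=float)[div_mask],
            position=pos,
        ))
    return traces


def write_traces_csv(traces: Sequence[CellTrace], path: str | Path) -> None:
    """Write CellTrace objects in the long-format trace dialect."""
    rows = []
    for tr in traces:
        sister = np.full(tr.frame_times.size, np.nan)
        sister[tr.division_frames] = tr.sister_first_values
        is_div = np.zeros(tr.frame_times.size, dtype=int)
        is_div[tr.division_frames] = 1
        for i in range(tr.frame_times.size):
            rows.append({
                "cell_id": tr.cell_id,
                "frame": i,
                "time_min": tr.frame_times[i],
                "fluor": tr.fluorescence[i],
                "is_division": is_div[i],
                "sister_fluor": sister[i],
                "x_um": tr.position[i, 0] if tr.position is not None else np.nan,
                "y_um": tr.position[i, 1] if tr.position is not None else np.nan,
            })
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(
        path, index=False, float_format="%.12g")
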