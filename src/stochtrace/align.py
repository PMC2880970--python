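"""Binning alignment and zero-order-hold resampling of replica traces.

Replicated SSA runs have different lengths and warped time vectors, so
pointwise cross-replica statistics are ill-defined on the raw samples.
Binning partitions each trace into consecutive half-open windows
[k*w, (k+1)*w) of fixed width w (anchored at the trace, or shared, start
time), replaces each non-empty window by one representative point
(t_rep, v_agg), and thereby puts every replica on a common grid.

Zero-order hold is the natural interpolant here: an SSA trace is exactly
piecewise constant between firings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .simulate import Trace, TraceSet

__all__ = [
    "Bin",
    "BinnedSeries",
    "AlignedSeries",
    "resample_uniform",
    "bin_series",
    "align_traceset",
    "AGGREGATES",
    "TIME_RULES",
]

AGGREGATES = ("sum", "mean", "max", "min")
TIME_RULES = ("median", "max_value")


@dataclass
class Bin:
    t_rep: float  # representative time, always one of the member times
    v_agg: float
    members: int
    window_index: int

    def __post_init__(self) -> None:
        if self.members < 1:
            raise ValueError("a bin needs at least one member point")


@dataclass
class BinnedSeries:
    species: str
    bins: list[Bin]
    window: float
    aggregate: str
    time_rule: str
    anchor: float  # start time of window 0

    @property
    def times(self) -> np.ndarray:
        return np.array([b.t_rep for b in self.bins])

    @property
    def values(self) -> np.ndarray:
        return np.array([b.v_agg for b in self.bins])


@dataclass
class AlignedSeries:
    """Per-replica binned values on one shared time vector (bin midpoints)."""

    species: str
    grid: np.ndarray  # shared time vector, one entry per surviving window
    values: np.ndarray  # shape (n_replicas, len(grid))
    window: float
    aggregate: str
    time_rule: str


def resample_uniform(
    trace: Trace, t_first: float, t_last: float, n_points: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a trace onto the uniform grid t_first + k*(t_last-t_first)/(n-1)
    by zero-order hold: the value at grid time g is the trace value at the
    latest event time <= g.

    Returns (grid_times, values) with values of shape (n_points, n_species).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if not t_first < t_last:
        raise ValueError("need t_first < t_last")
    if t_first < trace.t_first:
        raise ValueError("grid starts before the first recorded event")
    grid = t_first + np.arange(n_points) * ((t_last - t_first) / (n_points - 1))
    grid[-1] = t_last  # exact endpoint despite rounding
    idx = np.searchsorted(trace.times, grid, side="right") - 1
    return grid, trace.values[idx, :]


def _aggregate(vals: np.ndarray, how: str) -> float:
    if how == "sum":
        return float(vals.sum())
    if how == "mean":
        return float(vals.mean())
    if how == "max":
        return float(vals.max())
    if how == "min":
        return float(vals.min())
    raise ValueError(f"unknown aggregate {how!r} (choose from {AGGREGATES})")


def _representative_time(ts: np.ndarray, vals: np.ndarray, rule: str) -> float:
    if rule == "median":
        # lower median of the (already sorted) member times
        return float(ts[(len(ts) - 1) // 2])
    if rule == "max_value":
        return float(ts[int(np.argmax(vals))])
    raise ValueError(f"unknown time rule {rule!r} (choose from {TIME_RULES})")


def _bin_indices(times: np.ndarray, anchor: float, window: float) -> np.ndarray:
    """Half-open window index of each raw point: [anchor+k*w, anchor+(k+1)*w)."""
    return np.floor((times - anchor) / window).astype(int)


def bin_series(
    trace: Trace,
    species: str,
    window: float,
    aggregate: str = "mean",
    time_rule: str = "median",
    anchor: float | None = None,
) -> BinnedSeries:
    """Bin one species of one trace into fixed-width half-open time windows.

    Empty windows produce no bin.  The window grid is anchored at the trace
    start unless an explicit anchor is given (cross-replica alignment passes
    the common minimum start time).
    """
    if window <= 0 or not math.isfinite(window):
        raise ValueError("window width must be a positive finite real")
    vals = trace.column(species)
    if anchor is None:
        anchor = trace.t_first
    which = _bin_indices(trace.times, anchor, window)
    bins: list[Bin] = []
    for k in np.unique(which):
        m = which == k
        ts, vs = trace.times[m], vals[m]
        bins.append(
            Bin(
                t_rep=_representative_time(ts, vs, time_rule),
                v_agg=_aggregate(vs, aggregate),
                members=int(m.sum()),
                window_index=int(k),
            )
        )
    return BinnedSeries(
        species=species,
        bins=bins,
        window=window,
        aggregate=aggregate,
        time_rule=time_rule,
        anchor=float(anchor),
    )


def align_traceset(
    traces: TraceSet,
    species: str,
    window: float,
    aggregate: str = "mean",
    time_rule: str = "median",
) -> AlignedSeries:
    """Bin every replica with one shared window grid and keep only windows
    populated in all replicas, so the outputs share a single time vector.

    The grid is anchored at the minimum start time over the replica set and
    the shared time vector reports window midpoints; windows empty in any
    replica are dropped for all (intersection policy), which keeps pointwise
    cross-replica statistics defined at every reported time.
    """
    if species not in traces.species:
        raise ValueError(f"species {species!r} absent from the trace set")
    anchor = min(tr.t_first for tr in traces)
    binned = [
        bin_series(tr, species, window, aggregate, time_rule, anchor=anchor)
        for tr in traces
    ]
    shared = None
    for bs in binned:
        idx = {b.window_index for b in bs.bins}
        shared = idx if shared is None else (shared & idx)
    keep = sorted(shared or ())
    grid = anchor + (np.array(keep, dtype=float) + 0.5) * window
    values = np.empty((len(binned), len(keep)))
    for i, bs in enumerate(binned):
        by_idx = {b.window_index: b.v_agg for b in bs.bins}
        values[i, :] = [by_idx[k] for k in keep]
    return AlignedSeries(
        species=species,
        grid=grid,
        values=values,
        window=window,
        aggregate=aggregate,
        time_rule=time_rule,
    )
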