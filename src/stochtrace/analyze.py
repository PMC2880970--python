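"""Multi-trace ensemble analyzers.

Seven analyzers consume a replica set and produce time series or scalar
summaries: `series` (statistics across replicas at every timestamp seen in
any replica), `pointwise` (the same on a regular user grid), `first_hitting`
(statistics at the first time a boolean condition holds in each run),
`steady_state` (statistics at one random post-transient timestamp per run),
`cumulative` (max/min/time-average within condition-true intervals), `time`
(durations between condition fronts: oscillation periods, true-interval
lengths, total time-true), and `raw` (pass-through).

Cross-replica evaluation uses zero-order hold: an SSA trace is constant
between firings, so the value of a replica at any time t is its value at
the latest recorded timestamp <= t.

Conditions are boolean expressions over species comparisons, e.g.
``"S_CP < S_TF AND NOT (S_W = 0)"``.  A *front* is a timestamp where a
condition flips truth value: ascending when false -> true, descending when
true -> false.  The first timestamp of a trace never emits a front (there
is no pre-history), unless `initial_front=True` is requested.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .simulate import Trace, TraceSet

__all__ = [
    "STAT_NAMES",
    "Condition",
    "Comparison",
    "BoolOp",
    "NotOp",
    "ConditionSyntaxError",
    "StatDomainError",
    "Front",
    "AnalysisSeries",
    "FirstHittingResult",
    "CumulativeInterval",
    "CumulativeResult",
    "TimeAnalysisResult",
    "parse_condition",
    "compute_stat",
    "detect_fronts",
    "analyze_series",
    "analyze_pointwise",
    "analyze_first_hitting",
    "analyze_steady_state",
    "analyze_cumulative",
    "analyze_time",
    "analyze_raw",
]

STAT_NAMES = (
    "mean",
    "rms",
    "variance",
    "stddev",
    "stderr",
    "geometric_mean",
    "harmonic_mean",
    "skew",
    "kurtosis",
)


class ConditionSyntaxError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class StatDomainError(ValueError):
    """A statistic evaluated outside its domain (names the statistic)."""


# ---------------------------------------------------------------- conditions


class Condition:
    def evaluate(self, env: Mapping[str, float]) -> bool:
        raise NotImplementedError

    def species(self) -> set[str]:
        raise NotImplementedError


_OPS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "=": lambda a, b: a == b,
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
}


@dataclass
class Comparison(Condition):
    lhs: str  # species id
    op: str
    rhs: str | float  # species id or constant

    def evaluate(self, env: Mapping[str, float]) -> bool:
        if self.lhs not in env:
            raise KeyError(f"unknown species {self.lhs!r} in condition")
        left = env[self.lhs]
        if isinstance(self.rhs, str):
            if self.rhs not in env:
                raise KeyError(f"unknown species {self.rhs!r} in condition")
            right = env[self.rhs]
        else:
            right = self.rhs
        return _OPS[self.op](left, right)

    def species(self) -> set[str]:
        out = {self.lhs}
        if isinstance(self.rhs, str):
            out.add(self.rhs)
        return out


@dataclass
class BoolOp(Condition):
    op: str  # "and" | "or"
    terms: list[Condition]

    def evaluate(self, env: Mapping[str, float]) -> bool:
        if self.op == "and":
            return all(t.evaluate(env) for t in self.terms)
        return any(t.evaluate(env) for t in self.terms)

    def species(self) -> set[str]:
        return set().union(*(t.species() for t in self.terms))


@dataclass
class NotOp(Condition):
    term: Condition

    def evaluate(self, env: Mapping[str, float]) -> bool:
        return not self.term.evaluate(env)

    def species(self) -> set[str]:
        return self.term.species()


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)"
    r"|(?P<ident>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op><=|>=|!=|==|<|>|=)"
    r"|(?P<paren>[()]))"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ConditionSyntaxError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive descent over: expr := or_expr; or := and (OR and)*;
    and := unary (AND unary)*; unary := NOT unary | '(' expr ')' | cmp."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None, len(self.text))

    def _next(self):
        tok = self._peek()
        self.i += 1
        return tok

    def parse(self) -> Condition:
        expr = self._or()
        kind, val, pos = self._peek()
        if kind is not None:
            raise ConditionSyntaxError(f"unexpected token {val!r}", pos)
        return expr

    def _or(self) -> Condition:
        terms = [self._and()]
        while self._is_keyword("OR"):
            self._next()
            terms.append(self._and())
        return terms[0] if len(terms) == 1 else BoolOp("or", terms)

    def _and(self) -> Condition:
        terms = [self._unary()]
        while self._is_keyword("AND"):
            self._next()
            terms.append(self._unary())
        return terms[0] if len(terms) == 1 else BoolOp("and", terms)

    def _is_keyword(self, word: str) -> bool:
        kind, val, _ = self._peek()
        return kind == "ident" and val.upper() == word

    def _unary(self) -> Condition:
        kind, val, pos = self._peek()
        if kind == "ident" and val.upper() == "NOT":
            self._next()
            return NotOp(self._unary())
        if kind == "paren" and val == "(":
            self._next()
            expr = self._or()
            kind, val, pos = self._next()
            if val != ")":
                raise ConditionSyntaxError("expected ')'", pos)
            return expr
        return self._comparison()

    def _comparison(self) -> Condition:
        kind, val, pos = self._next()
        if kind != "ident":
            raise ConditionSyntaxError("expected a species identifier", pos)
        lhs = val
        kind, op, pos = self._next()
        if kind != "op":
            raise ConditionSyntaxError("expected a comparison operator", pos)
        kind, val, pos = self._next()
        if kind == "ident":
            rhs: str | float = val
        elif kind == "num":
            rhs = float(val)
        else:
            raise ConditionSyntaxError("expected a species or a number", pos)
        return Comparison(lhs, op, rhs)


def parse_condition(text: str) -> Condition:
    """Parse a boolean condition over species, e.g. ``"A > 600 AND B < A"``.

    Unknown species are only detected at evaluation time; syntax errors
    report the offending position.
    """
    return _Parser(text).parse()


# ---------------------------------------------------------------- statistics


def compute_stat(values: Sequence[float], stat: str) -> float:
    """One of the nine supported descriptive statistics of a value list.

    Conventions: variance/stddev/stderr use the unbiased (n-1) denominator;
    skew and kurtosis use population (1/n) central moments, with kurtosis
    reported as excess (normal -> 0); geometric and harmonic means require
    strictly positive values.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n == 0:
        raise StatDomainError(f"{stat}: empty value list")
    if stat == "mean":
        return float(x.mean())
    if stat == "rms":
        return float(np.sqrt(np.mean(x**2)))
    if stat in ("variance", "stddev", "stderr"):
        if n < 2:
            raise StatDomainError(f"{stat}: needs at least 2 values")
        var = float(x.var(ddof=1))
        if stat == "variance":
            return var
        sd = math.sqrt(var)
        return sd if stat == "stddev" else sd / math.sqrt(n)
    if stat == "geometric_mean":
        if (x <= 0).any():
            raise StatDomainError("geometric_mean: requires all values > 0")
        return float(np.exp(np.mean(np.log(x))))
    if stat == "harmonic_mean":
        if (x <= 0).any():
            raise StatDomainError("harmonic_mean: requires all values > 0")
        return float(n / np.sum(1.0 / x))
    if stat in ("skew", "kurtosis"):
        m = x.mean()
        m2 = float(np.mean((x - m) ** 2))
        if m2 == 0:
            raise StatDomainError(f"{stat}: undefined for constant values")
        if stat == "skew":
            m3 = float(np.mean((x - m) ** 3))
            return m3 / m2**1.5
        m4 = float(np.mean((x - m) ** 4))
        return m4 / m2**2 - 3.0
    raise ValueError(f"unknown statistic {stat!r} (choose from {STAT_NAMES})")


# ------------------------------------------------------------------- fronts


@dataclass
class Front:
    t: float
    direction: str  # "ascending" | "descending"


def _truth_vector(trace: Trace, condition: Condition) -> np.ndarray:
    needed = condition.species()
    cols = {s: trace.column(s) for s in trace.species if s in needed}
    missing = needed - set(cols)
    if missing:
        raise KeyError(f"unknown species in condition: {sorted(missing)}")
    out = np.empty(len(trace), dtype=bool)
    for i in range(len(trace)):
        out[i] = condition.evaluate({s: c[i] for s, c in cols.items()})
    return out


def detect_fronts(
    trace: Trace, condition: Condition, initial_front: bool = False
) -> list[Front]:
    """Timestamps where the condition flips truth value along one trace.

    Ascending = false -> true, descending = true -> false; fronts alternate
    by construction.  With ``initial_front`` a condition already true at the
    first timestamp counts as an ascending front there.
    """
    truth = _truth_vector(trace, condition)
    fronts: list[Front] = []
    if initial_front and len(truth) and truth[0]:
        fronts.append(Front(float(trace.times[0]), "ascending"))
    for i in range(1, len(truth)):
        if truth[i] != truth[i - 1]:
            fronts.append(
                Front(float(trace.times[i]), "ascending" if truth[i] else "descending")
            )
    return fronts


# ---------------------------------------------------------------- analyzers


@dataclass
class AnalysisSeries:
    species: str
    stat: str
    points: list[tuple[float, float, float | None]]  # (t, value, spread)
    n_runs_used: int
    label: str = ""

    @property
    def times(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def values(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


def _zoh_matrix(traces: TraceSet, species: str, grid: np.ndarray) -> np.ndarray:
    """Per-replica zero-order-hold values on a shared grid; grid times before
    a replica's first record clamp to its first value."""
    out = np.empty((len(traces), len(grid)))
    for i, tr in enumerate(traces):
        col = tr.column(species)
        idx = np.searchsorted(tr.times, grid, side="right") - 1
        out[i, :] = col[np.maximum(idx, 0)]
    return out


def _stats_on_grid(
    traces: TraceSet, species: str, stats: Sequence[str], grid: np.ndarray
) -> list[AnalysisSeries]:
    mat = _zoh_matrix(traces, species, grid)
    n = len(traces)
    out = []
    for stat in stats:
        pts: list[tuple[float, float, float | None]] = []
        for k, t in enumerate(grid):
            col = mat[:, k]
            try:
                v = compute_stat(col, stat)
            except StatDomainError:
                continue  # domain violation at this point: reported by omission
            spread = float(col.var(ddof=1)) if n >= 2 else None
            pts.append((float(t), v, spread))
        out.append(AnalysisSeries(species, stat, pts, n_runs_used=n))
    return out


def analyze_series(
    traces: TraceSet, species: Sequence[str], stats: Sequence[str]
) -> list[AnalysisSeries]:
    """Statistics across replicas at every timestamp present in any replica.

    The evaluation grid is the sorted union of all replica timestamps; each
    replica contributes its zero-order-hold value at each grid time.  One
    output series per (species, statistic); the optional spread entry is the
    cross-replica variance (error-bar material).
    """
    grid = np.unique(np.concatenate([tr.times for tr in traces]))
    out = []
    for sp in species:
        out.extend(_stats_on_grid(traces, sp, stats, grid))
    return out


def analyze_pointwise(
    traces: TraceSet,
    species: Sequence[str],
    stats: Sequence[str],
    interval: float,
) -> list[AnalysisSeries]:
    """Like `analyze_series` but on the regular grid t_min, t_min+d, ...;
    both span endpoints are always included."""
    if interval <= 0:
        raise ValueError("interval must be > 0")
    t_min = min(tr.t_first for tr in traces)
    t_max = max(tr.t_last for tr in traces)
    grid = np.arange(t_min, t_max, interval)
    if len(grid) == 0 or grid[-1] < t_max:
        grid = np.append(grid, t_max)
    out = []
    for sp in species:
        out.extend(_stats_on_grid(traces, sp, stats, grid))
    return out


@dataclass
class FirstHittingResult:
    species: str
    hit_times: list[float]
    hit_values: list[float]
    stats: dict[str, float]
    plotted_at: float | None  # mean hitting time
    n_runs_used: int
    n_runs_excluded: int


def analyze_first_hitting(
    traces: TraceSet,
    species: Sequence[str],
    stats: Sequence[str],
    condition: Condition,
) -> list[FirstHittingResult]:
    """Statistics of species values at the first timestamp (per run) where
    the condition holds.

    Runs that never satisfy the condition are excluded and counted; the
    aggregate is plotted at the mean hitting time.  Values are pooled across
    runs; the per-run (time, value) pairs are reported alongside.
    """
    results = []
    hit_index: list[tuple[Trace, int]] = []
    excluded = 0
    for tr in traces:
        truth = _truth_vector(tr, condition)
        hits = np.nonzero(truth)[0]
        if len(hits):
            hit_index.append((tr, int(hits[0])))
        else:
            excluded += 1
    for sp in species:
        times = [float(tr.times[i]) for tr, i in hit_index]
        vals = [float(tr.column(sp)[i]) for tr, i in hit_index]
        stat_out: dict[str, float] = {}
        for stat in stats:
            try:
                stat_out[stat] = compute_stat(vals, stat) if vals else math.nan
            except StatDomainError:
                continue
        results.append(
            FirstHittingResult(
                species=sp,
                hit_times=times,
                hit_values=vals,
                stats={} if not vals else stat_out,
                plotted_at=float(np.mean(times)) if times else None,
                n_runs_used=len(hit_index),
                n_runs_excluded=excluded,
            )
        )
    return results


def analyze_steady_state(
    traces: TraceSet,
    species: Sequence[str],
    stats: Sequence[str],
    transient: float,
    seed: int,
) -> dict[str, dict[str, float]]:
    """Statistics over one uniformly random post-transient timestamp per run.

    Assumes the ensemble is time-homogeneous after the transient, so any
    post-transient timestamp is an unbiased draw from the stationary regime.
    Reproducible for a fixed seed; runs that never pass the transient are
    excluded with a warning.
    """
    rng = np.random.default_rng(seed)
    picked: list[tuple[Trace, int]] = []
    for tr in traces:
        eligible = np.nonzero(tr.times > transient)[0]
        if len(eligible) == 0:
            warnings.warn(
                f"trace (seed={tr.seed}) has no timestamp beyond the transient "
                f"{transient}; excluded from steady-state statistics",
                stacklevel=2,
            )
            continue
        picked.append((tr, int(rng.choice(eligible))))
    out: dict[str, dict[str, float]] = {}
    for sp in species:
        vals = [float(tr.column(sp)[i]) for tr, i in picked]
        stat_out = {}
        for stat in stats:
            try:
                stat_out[stat] = compute_stat(vals, stat)
            except StatDomainError:
                continue
        out[sp] = stat_out
    return out


@dataclass
class CumulativeInterval:
    t_start: float
    t_end: float
    v_max: float
    v_min: float
    v_mean: float  # integral of the ZOH trace over the interval / length


@dataclass
class CumulativeResult:
    species: str
    replica: int
    intervals: list[CumulativeInterval]
    overall_max: float | None
    overall_min: float | None
    overall_mean: float | None  # total integral / total duration


def _true_intervals(trace: Trace, condition: Condition) -> list[tuple[float, float]]:
    """Maximal [a, b) spans where the ZOH condition signal is true; a span
    open at the end of the trace closes at the last timestamp."""
    truth = _truth_vector(trace, condition)
    spans = []
    start = None
    for i, tv in enumerate(truth):
        if tv and start is None:
            start = float(trace.times[i])
        elif not tv and start is not None:
            spans.append((start, float(trace.times[i])))
            start = None
    if start is not None and start < trace.t_last:
        spans.append((start, trace.t_last))
    return spans


def _zoh_integral(trace: Trace, species: str, a: float, b: float) -> float:
    """Exact integral of the piecewise-constant species signal over [a, b]."""
    ts, vs = trace.times, trace.column(species)
    knots = np.concatenate(([a], ts[(ts > a) & (ts < b)], [b]))
    idx = np.searchsorted(ts, knots[:-1], side="right") - 1
    seg_vals = vs[np.maximum(idx, 0)]
    return float(np.sum(seg_vals * np.diff(knots)))


def analyze_cumulative(
    traces: TraceSet, species: Sequence[str], condition: Condition
) -> list[CumulativeResult]:
    """Max, min and time-average of each species inside every maximal
    condition-true interval of each replica (trace treated as zero-order
    hold; the mean is the trace integral divided by the interval length),
    plus the aggregate over all of a replica's intervals."""
    results = []
    for ri, tr in enumerate(traces):
        spans = _true_intervals(tr, condition)
        for sp in species:
            col = tr.column(sp)
            intervals = []
            total_int = 0.0
            total_len = 0.0
            for a, b in spans:
                m = (tr.times >= a) & (tr.times <= b)
                member_vals = col[m]
                integral = _zoh_integral(tr, sp, a, b)
                intervals.append(
                    CumulativeInterval(
                        t_start=a,
                        t_end=b,
                        v_max=float(member_vals.max()),
                        v_min=float(member_vals.min()),
                        v_mean=integral / (b - a),
                    )
                )
                total_int += integral
                total_len += b - a
            results.append(
                CumulativeResult(
                    species=sp,
                    replica=ri,
                    intervals=intervals,
                    overall_max=max((iv.v_max for iv in intervals), default=None),
                    overall_min=min((iv.v_min for iv in intervals), default=None),
                    overall_mean=(total_int / total_len) if total_len else None,
                )
            )
    return results


@dataclass
class TimeAnalysisResult:
    replica: int
    mode: str
    durations: list[float]
    stats: dict[str, float]


TIME_MODES = ("between_ascending", "true_intervals", "time_sum")


def analyze_time(
    traces: TraceSet,
    condition: Condition,
    mode: str = "between_ascending",
    stats: Sequence[str] = (),
) -> list[TimeAnalysisResult]:
    """Durations derived from condition fronts, per replica.

    between_ascending: gaps between consecutive ascending fronts (oscillation
    periods).  true_intervals: each ascending front to the next descending
    front.  time_sum: a single duration, the total time the condition holds
    over the trace span.  Requested statistics are computed over the
    duration list (fewer than 2 fronts yields an empty list).
    """
    if mode not in TIME_MODES:
        raise ValueError(f"unknown mode {mode!r} (choose from {TIME_MODES})")
    results = []
    for ri, tr in enumerate(traces):
        if mode == "time_sum":
            durations = [sum(b - a for a, b in _true_intervals(tr, condition))]
        else:
            fronts = detect_fronts(tr, condition)
            if mode == "between_ascending":
                asc = [f.t for f in fronts if f.direction == "ascending"]
                durations = [b - a for a, b in zip(asc[:-1], asc[1:])]
            else:  # true_intervals
                durations = []
                for f, g in zip(fronts[:-1], fronts[1:]):
                    if f.direction == "ascending" and g.direction == "descending":
                        durations.append(g.t - f.t)
        stat_out = {}
        for stat in stats:
            try:
                stat_out[stat] = compute_stat(durations, stat)
            except StatDomainError:
                continue
        results.append(
            TimeAnalysisResult(replica=ri, mode=mode, durations=durations, stats=stat_out)
        )
    return results


def analyze_raw(traces: TraceSet, species: Sequence[str]) -> list[AnalysisSeries]:
    """Pass-through: each replica's (t, v) points, untouched."""
    out = []
    for ri, tr in enumerate(traces):
        for sp in species:
            col = tr.column(sp)
            pts = [(float(t), float(v), None) for t, v in zip(tr.times, col)]
            out.append(
                AnalysisSeries(sp, "raw", pts, n_runs_used=1, label=f"replica {ri}")
            )
    return out
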