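"""Independent brute-force oracles, written straight from the definitions.

Plain-Python loops only: no shared code paths with the package internals
(the shared surface is limited to the Trace/TraceSet containers and the
condition AST's `evaluate`, which are inputs, not logic under test).
"""

from __future__ import annotations

import math

import numpy as np


def bf_stat(values, name):
    xs = [float(v) for v in values]
    n = len(xs)
    mean = sum(xs) / n
    if name == "mean":
        return mean
    if name == "rms":
        return math.sqrt(sum(x * x for x in xs) / n)
    if name in ("variance", "stddev", "stderr"):
        var = sum((x - mean) ** 2 for x in xs) / (n - 1)
        if name == "variance":
            return var
        if name == "stddev":
            return math.sqrt(var)
        return math.sqrt(var) / math.sqrt(n)
    if name == "geometric_mean":
        return math.exp(sum(math.log(x) for x in xs) / n)
    if name == "harmonic_mean":
        return n / sum(1.0 / x for x in xs)
    m2 = sum((x - mean) ** 2 for x in xs) / n
    if name == "skew":
        m3 = sum((x - mean) ** 3 for x in xs) / n
        return m3 / m2**1.5
    if name == "kurtosis":
        m4 = sum((x - mean) ** 4 for x in xs) / n
        return m4 / m2**2 - 3.0
    raise ValueError(name)


def bf_stat_ok(values, name):
    """Domain check mirroring the stated preconditions."""
    n = len(values)
    if n == 0:
        return False
    if name in ("variance", "stddev", "stderr") and n < 2:
        return False
    if name in ("geometric_mean", "harmonic_mean") and any(v <= 0 for v in values):
        return False
    if name in ("skew", "kurtosis"):
        mean = sum(values) / n
        if all(v == mean for v in values):
            return False
    return True


def bf_zoh(times, values, t):
    """Value at the latest recorded time <= t (clamped to the first record)."""
    out = values[0]
    for tt, vv in zip(times, values):
        if tt <= t:
            out = vv
        else:
            break
    return out


def bf_truth(trace, condition):
    out = []
    for i in range(len(trace.times)):
        env = {s: trace.values[i, k] for k, s in enumerate(trace.species)}
        out.append(bool(condition.evaluate(env)))
    return out


def bf_fronts(trace, condition):
    truth = bf_truth(trace, condition)
    fronts = []
    for i in range(1, len(truth)):
        if truth[i] and not truth[i - 1]:
            fronts.append((float(trace.times[i]), "ascending"))
        elif truth[i - 1] and not truth[i]:
            fronts.append((float(trace.times[i]), "descending"))
    return fronts


def bf_series_grid(traces):
    return sorted({float(t) for tr in traces for t in tr.times})


def bf_stats_on_grid(traces, species, stats, grid):
    """(stat -> list of (t, value)) across replicas, ZOH at grid times."""
    k = traces.traces[0].species.index(species)
    out = {s: [] for s in stats}
    for t in grid:
        col = [
            bf_zoh(list(tr.times), list(tr.values[:, k]), t) for tr in traces
        ]
        for s in stats:
            if bf_stat_ok(col, s):
                out[s].append((t, bf_stat(col, s)))
    return out


def bf_pointwise_grid(traces, interval):
    t_min = min(float(tr.times[0]) for tr in traces)
    t_max = max(float(tr.times[-1]) for tr in traces)
    grid, t = [], t_min
    while t < t_max:
        grid.append(t)
        t += interval
    grid.append(t_max)
    return grid


def bf_first_hitting(traces, species, stats, condition):
    hits = []
    excluded = 0
    for tr in traces:
        truth = bf_truth(tr, condition)
        if True in truth:
            hits.append((tr, truth.index(True)))
        else:
            excluded += 1
    out = {}
    for sp in species:
        k = traces.traces[0].species.index(sp)
        times = [float(tr.times[i]) for tr, i in hits]
        vals = [float(tr.values[i, k]) for tr, i in hits]
        stat_out = {
            s: bf_stat(vals, s) for s in stats if vals and bf_stat_ok(vals, s)
        }
        out[sp] = {
            "times": times,
            "values": vals,
            "stats": stat_out,
            "plotted_at": sum(times) / len(times) if times else None,
            "n_used": len(hits),
            "n_excluded": excluded,
        }
    return out


def bf_steady_state(traces, species, stats, transient, seed):
    """Replays the documented sampling rule: one uniform post-transient
    timestamp per run from numpy's seeded generator, in replica order."""
    rng = np.random.default_rng(seed)
    picked = []
    for tr in traces:
        eligible = [i for i, t in enumerate(tr.times) if t > transient]
        if not eligible:
            continue
        picked.append((tr, int(rng.choice(np.array(eligible)))))
    out = {}
    for sp in species:
        k = traces.traces[0].species.index(sp)
        vals = [float(tr.values[i, k]) for tr, i in picked]
        out[sp] = {s: bf_stat(vals, s) for s in stats if bf_stat_ok(vals, s)}
    return out


def bf_true_intervals(trace, condition):
    truth = bf_truth(trace, condition)
    spans, start = [], None
    for i, tv in enumerate(truth):
        if tv and start is None:
            start = float(trace.times[i])
        if not tv and start is not None:
            spans.append((start, float(trace.times[i])))
            start = None
    if start is not None and start < float(trace.times[-1]):
        spans.append((start, float(trace.times[-1])))
    return spans


def bf_integral(trace, k, a, b):
    """Integral of the ZOH signal of species column k over [a, b]."""
    total = 0.0
    ts = list(trace.times) + [math.inf]
    vs = list(trace.values[:, k])
    for i in range(len(vs)):
        lo = max(ts[i], a)
        hi = min(ts[i + 1], b)
        if hi > lo:
            total += vs[i] * (hi - lo)
    # portion of [a,b] before the first record holds the first value
    if a < ts[0]:
        total += vs[0] * (min(ts[0], b) - a)
    return total


def bf_cumulative(traces, species, condition):
    out = []
    for ri, tr in enumerate(traces):
        spans = bf_true_intervals(tr, condition)
        for sp in species:
            k = tr.species.index(sp)
            ivs = []
            tot_i = tot_l = 0.0
            for a, b in spans:
                members = [
                    float(tr.values[i, k])
                    for i, t in enumerate(tr.times)
                    if a <= t <= b
                ]
                integral = bf_integral(tr, k, a, b)
                ivs.append(
                    {
                        "a": a,
                        "b": b,
                        "max": max(members),
                        "min": min(members),
                        "mean": integral / (b - a),
                    }
                )
                tot_i += integral
                tot_l += b - a
            out.append(
                {
                    "species": sp,
                    "replica": ri,
                    "intervals": ivs,
                    "overall_max": max((iv["max"] for iv in ivs), default=None),
                    "overall_min": min((iv["min"] for iv in ivs), default=None),
                    "overall_mean": tot_i / tot_l if tot_l else None,
                }
            )
    return out


def bf_time(traces, condition, mode):
    out = []
    for tr in traces:
        if mode == "time_sum":
            durations = [sum(b - a for a, b in bf_true_intervals(tr, condition))]
        else:
            fronts = bf_fronts(tr, condition)
            if mode == "between_ascending":
                asc = [t for t, d in fronts if d == "ascending"]
                durations = [asc[i + 1] - asc[i] for i in range(len(asc) - 1)]
            else:
                durations = []
                for i in range(len(fronts) - 1):
                    if fronts[i][1] == "ascending" and fronts[i + 1][1] == "descending":
                        durations.append(fronts[i + 1][0] - fronts[i][0])
        out.append(durations)
    return out


def bf_degree_scores(edges, nodes, mode):
    """Normalized degree from a raw edge list (with multiplicity)."""
    deg = {v: 0 for v in nodes}
    for u, v in edges:
        if mode in ("out", "total"):
            deg[u] += 1
        if mode in ("in", "total"):
            deg[v] += 1
    n = len(nodes)
    return {v: d / (n - 1) for v, d in deg.items()}


def bf_bins(times, values, window, anchor, aggregate, time_rule):
    """Direct enumeration of half-open fixed-width bins."""
    groups = {}
    for t, v in zip(times, values):
        k = math.floor((t - anchor) / window)
        groups.setdefault(k, []).append((float(t), float(v)))
    out = []
    for k in sorted(groups):
        pts = groups[k]
        ts = sorted(t for t, _ in pts)
        vs = [v for _, v in pts]
        if aggregate == "sum":
            agg = sum(vs)
        elif aggregate == "mean":
            agg = sum(vs) / len(vs)
        elif aggregate == "max":
            agg = max(vs)
        else:
            agg = min(vs)
        if time_rule == "median":
            t_rep = ts[(len(ts) - 1) // 2]
        else:
            t_rep = pts[max(range(len(pts)), key=lambda i: pts[i][1])][0]
        out.append((k, t_rep, agg, len(pts)))
    return out
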