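"""Exact stochastic simulation (Gillespie direct method) and replica ensembles.

The simulator samples the next-reaction density: given state x at time t the
waiting time tau is exponential with rate a0(x) = sum_j a_j(x) and the firing
channel j is drawn with probability a_j(x)/a0(x), independently of tau.
Traces record the state at t=0 and after every firing (no thinning), so they
are piecewise-constant, unevenly sampled signals.

This module doubles as the repository's synthetic-fixture generator: the
ensembles every other module is tested on come from `simulate_replicas` on
the fixture models of :mod:`stochtrace.model`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .model import Reaction, ReactionModel, SystemState

__all__ = [
    "Trace",
    "TraceSet",
    "propensity",
    "ssa_step",
    "simulate_ssa",
    "simulate_replicas",
    "derive_seeds",
]

# golden-ratio stride for sub-seed splitting (see derive_seeds)
_SEED_STRIDE = 0x9E3779B9
_SEED_MOD = 1 << 63


@dataclass
class Trace:
    """One replica: strictly increasing times and per-species value columns."""

    species: list[str]
    times: np.ndarray  # shape (T,)
    values: np.ndarray  # shape (T, n_species)
    seed: int | None = None
    _tstart: dict[str, float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.times),
            len(self.species),
        ):
            raise ValueError("values must have shape (len(times), len(species))")
        if len(self.times) and (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")

    def column(self, species: str) -> np.ndarray:
        try:
            return self.values[:, self.species.index(species)]
        except ValueError:
            raise KeyError(f"species {species!r} not in trace") from None

    @property
    def tstart(self) -> dict[str, float]:
        """First time each species' amount is > 0 (0 if initially present,
        +inf if never)."""
        if self._tstart is None:
            out: dict[str, float] = {}
            for k, sid in enumerate(self.species):
                pos = np.nonzero(self.values[:, k] > 0)[0]
                out[sid] = float(self.times[pos[0]]) if len(pos) else math.inf
            self._tstart = out
        return self._tstart

    @property
    def t_first(self) -> float:
        return float(self.times[0])

    @property
    def t_last(self) -> float:
        return float(self.times[-1])

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class TraceSet:
    """Replicas of the same model from independently seeded runs."""

    traces: list[Trace]
    model_ref: str = ""

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValueError("a TraceSet needs at least one trace")
        sp = self.traces[0].species
        for tr in self.traces[1:]:
            if tr.species != sp:
                raise ValueError("all traces in a set must share the species set")

    @property
    def species(self) -> list[str]:
        return self.traces[0].species

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[Trace]:
        return iter(self.traces)

    def pooled_tstart(self) -> dict[str, float]:
        """Per species, the earliest first-appearance time over all replicas."""
        out: dict[str, float] = {}
        for sid in self.species:
            out[sid] = min(tr.tstart[sid] for tr in self.traces)
        return out


def propensity(reaction: Reaction, state: SystemState) -> float:
    """Mass-action propensity a_j(x) of one reaction in the given state.

    Order 0 -> c; order 1 (reactant S) -> c*x_S; order 2 with distinct
    reactants -> c*x_S1*x_S2; homodimer 2S -> c*x_S*(x_S-1)/2 (unordered
    reactant pairs).
    """
    c = reaction.rate_constant
    rs = reaction.reactants
    for sid in rs:
        if sid not in state.x:
            raise KeyError(f"reactant {sid!r} missing from state")
        if state.x[sid] < 0:
            raise ValueError(f"invalid state: negative amount for {sid!r}")
    if len(rs) == 0:
        return c
    if len(rs) == 1:
        return c * state.x[rs[0]]
    if rs[0] == rs[1]:
        x = state.x[rs[0]]
        return c * x * (x - 1) / 2.0
    return c * state.x[rs[0]] * state.x[rs[1]]


def ssa_step(
    state: SystemState, reactions: list[Reaction], rng: np.random.Generator
) -> tuple[float, int] | None:
    """Sample one (tau, j) jump of the direct method, or None on termination.

    tau ~ Exponential(a0) with a0 the total propensity; j is drawn with
    probability a_j/a0 independently of tau.  Returns None when a0 == 0
    (no reaction can fire).
    """
    a = [propensity(r, state) for r in reactions]
    a0 = float(sum(a))
    if a0 <= 0.0:
        return None
    tau = rng.exponential(1.0 / a0)
    # inverse-CDF draw over the discrete channel distribution
    u = rng.random() * a0
    acc = 0.0
    j = len(a) - 1
    for k, ak in enumerate(a):
        acc += ak
        if u < acc:
            j = k
            break
    return tau, j


def simulate_ssa(
    model: ReactionModel,
    t_max: float,
    seed: int,
    max_steps: int | None = None,
) -> Trace:
    """Run one exact SSA trajectory until t >= t_max, exhaustion of events,
    or (optionally) `max_steps` firings.

    The same (model, t_max, seed) always yields a bit-identical trace.
    """
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    rng = np.random.default_rng(seed)
    sids = model.species_ids
    index = {sid: k for k, sid in enumerate(sids)}
    x = np.array([s.initial_amount for s in model.species], dtype=float)

    # flatten reactions for the hot loop
    flat = []
    for r in model.reactions:
        delta = np.zeros(len(sids))
        for sid, d in r.change_vector.items():
            delta[index[sid]] = d
        rs = [index[s] for s in r.reactants]
        flat.append((r.rate_constant, rs, delta))

    times = [0.0]
    records = [x.copy()]
    t = 0.0
    n_steps = 0
    while t < t_max and (max_steps is None or n_steps < max_steps):
        a = np.empty(len(flat))
        for k, (c, rs, _) in enumerate(flat):
            if not rs:
                a[k] = c
            elif len(rs) == 1:
                a[k] = c * x[rs[0]]
            elif rs[0] == rs[1]:
                a[k] = c * x[rs[0]] * (x[rs[0]] - 1) / 2.0
            else:
                a[k] = c * x[rs[0]] * x[rs[1]]
        a0 = a.sum()
        if a0 <= 0.0:
            break
        tau = rng.exponential(1.0 / a0)
        if t + tau > t_max:
            break
        u = rng.random() * a0
        j = int(np.searchsorted(np.cumsum(a), u, side="right"))
        j = min(j, len(flat) - 1)
        t += tau
        x = x + flat[j][2]
        if (x < 0).any():
            raise RuntimeError(
                "internal error: reaction drove an amount negative"
            )  # pragma: no cover - unreachable with correct propensities
        times.append(t)
        records.append(x.copy())
        n_steps += 1
    return Trace(
        species=list(sids),
        times=np.array(times),
        values=np.array(records),
        seed=int(seed),
    )


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """Pairwise-distinct deterministic sub-seeds: a golden-ratio stride
    offset from the base seed, reduced mod 2^63 (the stride keeps offsets
    distinct; PCG64 then mixes each seed thoroughly)."""
    return [(int(base_seed) + i * _SEED_STRIDE) % _SEED_MOD for i in range(n)]


def simulate_replicas(
    model: ReactionModel,
    t_max: float,
    n: int,
    base_seed: int,
    max_steps: int | None = None,
) -> TraceSet:
    """n independently seeded SSA replicas of the same model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    seeds = derive_seeds(base_seed, n)
    traces = [simulate_ssa(model, t_max, s, max_steps=max_steps) for s in seeds]
    return TraceSet(traces=traces, model_ref=model.name)
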