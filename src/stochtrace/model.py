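"""Reaction-network model types.

A :class:`ReactionModel` is a well-stirred set of chemical species coupled by
mass-action reactions of order 0-2.  Species come in three kinds: ``entity``
and ``complex`` carry integer copy numbers, ``variable`` carries a real-valued
scalar measurement (mass, temperature, volume, ...).  Each reaction holds a
stochastic rate constant ``c`` and a signed stoichiometric change vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections import Counter
from typing import Mapping, Sequence

__all__ = [
    "Species",
    "Reaction",
    "ReactionModel",
    "SystemState",
    "make_fixture_model",
]

_SPECIES_KINDS = ("entity", "complex", "variable")


@dataclass
class Species:
    """One chemical species.

    Parameters
    ----------
    id : str
        Unique identifier within a model.
    kind : {"entity", "complex", "variable"}
        Entities and complexes are discrete populations; variables are
        destructured scalar measurements.
    initial_amount : float
        Non-negative; integral for entities/complexes.
    annotations : list of (key, URI) pairs
        MIRIAM-style data-source annotations carried through I/O and graphs.
    """

    id: str
    kind: str = "entity"
    initial_amount: float = 0.0
    annotations: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in _SPECIES_KINDS:
            raise ValueError(f"unknown species kind {self.kind!r}")
        if self.initial_amount < 0:
            raise ValueError(f"species {self.id!r}: initial amount must be >= 0")
        if self.kind != "variable" and self.initial_amount != int(self.initial_amount):
            raise ValueError(
                f"species {self.id!r}: {self.kind} amounts must be integers"
            )


@dataclass
class Reaction:
    """A mass-action reaction of total reactant order 0, 1 or 2.

    ``reactants`` and ``products`` are multisets of species ids (a homodimer
    reaction 2A -> C lists ``["A", "A"]``).  ``rtype`` is a free-text category
    tag (monomolecular, bimolecular, degradation, ...).  The change vector is
    derived as products-minus-reactants multiplicities.
    """

    id: str
    reactants: Sequence[str]
    products: Sequence[str]
    rate_constant: float
    rtype: str = ""

    def __post_init__(self) -> None:
        if self.rate_constant <= 0:
            raise ValueError(f"reaction {self.id!r}: rate constant must be > 0")
        if len(self.reactants) > 2:
            raise ValueError(
                f"reaction {self.id!r}: mass-action orders 0-2 only "
                f"(got total reactant multiplicity {len(self.reactants)})"
            )
        self.reactants = list(self.reactants)
        self.products = list(self.products)

    @property
    def order(self) -> int:
        return len(self.reactants)

    @property
    def change_vector(self) -> dict[str, int]:
        """Signed stoichiometric change per species (zero entries omitted)."""
        delta: Counter[str] = Counter(self.products)
        delta.subtract(Counter(self.reactants))
        return {s: d for s, d in delta.items() if d != 0}


@dataclass
class ReactionModel:
    species: list[Species]
    reactions: list[Reaction]
    name: str = "model"

    def __post_init__(self) -> None:
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species ids in model")
        known = set(ids)
        for r in self.reactions:
            for sid in list(r.reactants) + list(r.products):
                if sid not in known:
                    raise ValueError(
                        f"reaction {r.id!r} references unknown species {sid!r}"
                    )

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def species_by_id(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def initial_state(self) -> "SystemState":
        return SystemState(t=0.0, x={s.id: s.initial_amount for s in self.species})


@dataclass
class SystemState:
    """Time plus current per-species amounts (the state propensities see)."""

    t: float
    x: dict[str, float]

    def validate(self) -> None:
        if self.t < 0 or not math.isfinite(self.t):
            raise ValueError("state time must be finite and >= 0")
        for sid, v in self.x.items():
            if v < 0:
                raise ValueError(f"negative amount for species {sid!r}")


def make_fixture_model(kind: str, params: Mapping[str, float] | None = None) -> ReactionModel:
    """Build one of the built-in fixture models.

    kind = "birth_death"
        A single species S with a zeroth-order synthesis (rate ``birth``) and
        a first-order decay (rate ``death`` per molecule); stationary mean is
        birth/death.
    kind = "dimerisation"
        Reversible dimerisation 2A <-> C with association rate ``c_on`` and
        dissociation rate ``c_off``.
    kind = "oscillator"
        A three-species negative-feedback loop.  Species C is absent at t=0
        and only enters the system through a synthesis step, so the fixture
        exercises first-appearance (tstart) bookkeeping and the
        temporal-circuit layout.
    """
    p = dict(params or {})

    def take(key: str, default: float) -> float:
        return float(p.pop(key, default))

    if kind == "birth_death":
        birth = take("birth", 10.0)
        death = take("death", 0.1)
        x0 = take("x0", 0.0)
        model = ReactionModel(
            species=[Species("S", "entity", x0)],
            reactions=[
                Reaction("birth", [], ["S"], birth, rtype="synthesis"),
                Reaction("death", ["S"], [], death, rtype="degradation"),
            ],
            name="birth_death",
        )
    elif kind == "dimerisation":
        c_on = take("c_on", 0.01)
        c_off = take("c_off", 0.1)
        a0 = take("a0", 100.0)
        c0 = take("c0", 0.0)
        model = ReactionModel(
            species=[Species("A", "entity", a0), Species("C", "complex", c0)],
            reactions=[
                Reaction("dimerise", ["A", "A"], ["C"], c_on, rtype="bimolecular"),
                Reaction("dissociate", ["C"], ["A", "A"], c_off, rtype="monomolecular"),
            ],
            name="dimerisation",
        )
    elif kind == "oscillator":
        # A activates B, B activates C (C starts absent), C represses A via
        # an enhanced degradation channel: a crude negative-feedback loop.
        k_a = take("k_a", 50.0)
        k_b = take("k_b", 0.5)
        k_c = take("k_c", 0.5)
        d = take("d", 0.2)
        k_rep = take("k_rep", 0.02)
        a0 = take("a0", 10.0)
        b0 = take("b0", 5.0)
        model = ReactionModel(
            species=[
                Species("A", "entity", a0),
                Species("B", "entity", b0),
                Species("C", "entity", 0.0),
            ],
            reactions=[
                Reaction("syn_A", [], ["A"], k_a, rtype="synthesis"),
                Reaction("act_B", ["A"], ["A", "B"], k_b, rtype="monomolecular"),
                Reaction("act_C", ["B"], ["B", "C"], k_c, rtype="monomolecular"),
                Reaction("deg_A", ["A"], [], d, rtype="degradation"),
                Reaction("deg_B", ["B"], [], d, rtype="degradation"),
                Reaction("deg_C", ["C"], [], d, rtype="degradation"),
                Reaction("rep_A", ["C", "A"], ["C"], k_rep, rtype="bimolecular"),
            ],
            name="oscillator",
        )
    else:
        raise ValueError(f"unknown fixture model kind {kind!r}")
    if p:
        raise ValueError(f"unknown parameters for {kind!r}: {sorted(p)}")
    return model
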