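from __future__ import annotations

import numpy as np
import pytest

from stochtrace.model import make_fixture_model
from stochtrace.simulate import Trace, TraceSet, simulate_replicas


def make_trace(times, columns: dict[str, list[float]], seed=None) -> Trace:
    sids = list(columns)
    values = np.column_stack([np.asarray(columns[s], dtype=float) for s in sids])
    return Trace(species=sids, times=np.asarray(times, dtype=float), values=values, seed=seed)


def fuzz_traceset(rng: np.random.Generator, n_species=2, n_replicas=3, max_len=40) -> TraceSet:
    """Random replica set: distinct sorted times, small integer values;
    replicas deliberately differ in length and time grid."""
    sids = [f"S{i}" for i in range(n_species)]
    traces = []
    for r in range(n_replicas):
        n = int(rng.integers(3, max_len))
        times = np.sort(rng.uniform(0.0, 10.0, size=n))
        times = np.unique(np.round(times, 6))
        vals = rng.integers(0, 8, size=(len(times), n_species)).astype(float)
        traces.append(Trace(species=sids, times=times, values=vals, seed=r))
    return TraceSet(traces=traces)


@pytest.fixture
def birth_death_model():
    return make_fixture_model("birth_death", {"birth": 10.0, "death": 0.1})


@pytest.fixture
def oscillator_model():
    return make_fixture_model("oscillator")


@pytest.fixture
def small_ensemble(birth_death_model):
    return simulate_replicas(birth_death_model, t_max=5.0, n=4, base_seed=7)
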