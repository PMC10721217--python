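import numpy as np
import pytest

from synspread.circuit_sim import SyntheticCircuit
from synspread.spread_model import MultiplicityMix


@pytest.fixture
def tiny_circuit() -> SyntheticCircuit:
    """One starter, three inputs with multiplicities 1, 2, 3 (6 contacts)."""
    return SyntheticCircuit(
        starters=[("s0", (0.0, 0.0, 0.0))],
        inputs=["i0", "i1", "i2"],
        contacts=[("i0", "s0", 1), ("i1", "s0", 2), ("i2", "s0", 3)],
    )


def make_two_population_circuit(n_inputs: int, R: float, Ma: int, Mb: int) -> SyntheticCircuit:
    """Single-starter circuit with inputs split Ma:Mb in neuron ratio R : 1."""
    n_a = int(round(n_inputs * R / (R + 1.0)))
    contacts = []
    inputs = []
    for i in range(n_inputs):
        iid = f"i{i}"
        inputs.append(iid)
        contacts.append((iid, "s0", Ma if i < n_a else Mb))
    return SyntheticCircuit(
        starters=[("s0", (0.0, 0.0, 0.0))], inputs=inputs, contacts=contacts
    )


def make_shared_circuit(n_inputs: int, shared_fraction: float, seed: int) -> SyntheticCircuit:
    """Two starters with ``n_inputs`` single-contact inputs each; a planted
    fraction of the *subject* starter's (``s1``) inputs also contacts the
    neighbor ``s0``.  Sharing is one-directional so that the subject's
    contacts all come from its own inputs and its shared-input fraction is
    exactly the planted one (the premise of the first-order excess formula)."""
    rng = np.random.default_rng(seed)
    inputs, contacts = [], []
    for i in range(n_inputs):  # neighbor's private inputs
        iid = f"i0_{i}"
        inputs.append(iid)
        contacts.append((iid, "s0", 1))
    for i in range(n_inputs):  # subject's inputs, some shared with s0
        iid = f"i1_{i}"
        inputs.append(iid)
        contacts.append((iid, "s1", 1))
        if rng.random() < shared_fraction:
            contacts.append((iid, "s0", 1))
    return SyntheticCircuit(
        starters=[("s0", (0.0, 0.0, 0.0)), ("s1", (40.0, 0.0, 0.0))],
        inputs=inputs,
        contacts=contacts,
    )


def subject_sf_replicates(circuit, U, n_reps, seed, starter="s1"):
    """Mean/SE of one starter's SF over independent replicate simulations."""
    from synspread.circuit_sim import simulate_spread

    children = np.random.SeedSequence(seed).spawn(n_reps)
    sfs = np.array([
        simulate_spread(circuit, U, int(c.generate_state(1)[0])).sf_per_starter[starter]
        for c in children
    ])
    return float(sfs.mean()), float(sfs.std(ddof=1) / np.sqrt(n_reps))


@pytest.fixture
def em_like_mix() -> MultiplicityMix:
    return MultiplicityMix([(1, 0.92), (2, 0.067), (3, 0.013)])
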