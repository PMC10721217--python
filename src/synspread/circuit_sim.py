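"""Stochastic tracer spread over an explicit starter/input contact graph.

Brute-force counterpart of the closed-form model: every individual synaptic
contact is crossed independently with probability ``U``; an input neuron is
labeled iff at least one of its contacts (onto any starter) is crossed; every
contact of a labeled input neuron counts as presynaptically marked — including
contacts that were never themselves crossed.  That last rule is precisely the
mechanism behind shared-input inflation of the synaptic fraction.

Random draws are per-contact uniforms compared against ``U``, so outcomes at
a larger ``U`` with the same seed label a superset of inputs (monotone
coupling), and replicate streams in :func:`estimate_metrics` are spawned from
one root seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticCircuit",
    "SpreadOutcome",
    "MetricsEstimate",
    "simulate_spread",
    "estimate_metrics",
    "read_circuit_tsv",
    "write_circuit_tsv",
    "write_starters_csv",
    "read_starters_csv",
]


@dataclass
class SyntheticCircuit:
    """Explicit contact graph between input neurons and starter cells.

    Fields
    ------
    starters : list of (id, (x_um, y_um, z_um))
    inputs : list of input neuron ids
    contacts : list of (input_id, starter_id, n_contacts)
        One record per connection; ``n_contacts`` is its multiplicity.
    starter_inputs : optional set of input ids that are themselves starters
        (hook for representing direct starter-to-starter connections).
    """

    starters: List[Tuple[str, Tuple[float, float, float]]]
    inputs: List[str]
    contacts: List[Tuple[str, str, int]]
    starter_inputs: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        starter_ids = [s for s, _ in self.starters]
        if len(set(starter_ids)) != len(starter_ids):
            raise ValueError("duplicate starter ids")
        if len(set(self.inputs)) != len(self.inputs):
            raise ValueError("duplicate input ids")
        starter_set, input_set = set(starter_ids), set(self.inputs)
        seen_pairs = set()
        touched = set()
        for inp, st, n in self.contacts:
            if inp not in input_set:
                raise ValueError(f"contact references unknown input id {inp!r}")
            if st not in starter_set:
                raise ValueError(f"contact references unknown starter id {st!r}")
            if n < 1 or n != int(n):
                raise ValueError(f"n_contacts must be an integer >= 1, got {n!r}")
            if (inp, st) in seen_pairs:
                raise ValueError(f"duplicate (input, starter) pair ({inp!r}, {st!r})")
            seen_pairs.add((inp, st))
            touched.add(inp)
        missing = input_set - touched
        if missing:
            raise ValueError(
                f"{len(missing)} input(s) appear in no contact record, "
                f"e.g. {sorted(missing)[:3]}"
            )
        self._cache: Optional[dict] = None

    @property
    def n_total_contacts(self) -> int:
        return sum(n for _, _, n in self.contacts)

    def _arrays(self) -> dict:
        """Index arrays for vectorized simulation (built once, cached)."""
        if self._cache is None:
            input_index = {inp: i for i, inp in enumerate(self.inputs)}
            starter_index = {s: i for i, (s, _) in enumerate(self.starters)}
            rec_input = np.array([input_index[i] for i, _, _ in self.contacts], dtype=np.int64)
            rec_starter = np.array([starter_index[s] for _, s, _ in self.contacts], dtype=np.int64)
            rec_n = np.array([n for _, _, n in self.contacts], dtype=np.int64)
            offsets = np.concatenate([[0], np.cumsum(rec_n)])
            # per-individual-contact record id
            contact_record = np.repeat(np.arange(len(rec_n)), rec_n)
            contacts_per_starter = np.bincount(
                rec_starter, weights=rec_n, minlength=len(self.starters)
            ).astype(np.int64)
            self._cache = {
                "rec_input": rec_input,
                "rec_starter": rec_starter,
                "rec_n": rec_n,
                "contact_record": contact_record,
                "contacts_per_starter": contacts_per_starter,
            }
        return self._cache


@dataclass(frozen=True)
class SpreadOutcome:
    """Result of one simulated tracing experiment."""

    labeled_inputs: FrozenSet[str]
    labeled_contacts_per_starter: Dict[str, Tuple[int, int]]  # starter -> (S*, S)
    sf_per_starter: Dict[str, float]
    if_overall: float
    convergence_index: float
    U: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "U": self.U,
            "seed": self.seed,
            "n_labeled_inputs": len(self.labeled_inputs),
            "labeled_contacts_per_starter": {
                k: list(v) for k, v in self.labeled_contacts_per_starter.items()
            },
            "sf_per_starter": dict(self.sf_per_starter),
            "if_overall": self.if_overall,
            "convergence_index": self.convergence_index,
        }


def simulate_spread(
    circuit: SyntheticCircuit,
    U: float,
    seed: int,
    *,
    u_per_contact: Optional[Mapping[Tuple[str, str], float]] = None,
) -> SpreadOutcome:
    """Simulate one tracing experiment; deterministic given ``seed``.

    Each individual contact is crossed independently with probability ``U``
    (or a per-connection override from ``u_per_contact``, a hook for
    position-dependent efficiencies).  An input is labeled iff any of its
    contacts onto any starter is crossed; all contacts of a labeled input are
    counted as labeled.
    """
    if not (0.0 <= U <= 1.0) or math.isnan(U):
        raise ValueError(f"U must lie in [0, 1], got {U!r}")
    arrays = circuit._arrays()
    rng = np.random.default_rng(seed)
    draws = rng.random(int(arrays["rec_n"].sum()))

    if u_per_contact is None:
        per_contact_u = U
    else:
        u_by_record = np.array(
            [u_per_contact.get((inp, st), U) for inp, st, _ in circuit.contacts]
        )
        per_contact_u = u_by_record[arrays["contact_record"]]

    crossed = draws < per_contact_u
    record_crossed = np.bincount(
        arrays["contact_record"][crossed], minlength=len(circuit.contacts)
    ) > 0
    input_labeled = np.zeros(len(circuit.inputs), dtype=bool)
    input_labeled[arrays["rec_input"][record_crossed]] = True

    record_labeled = input_labeled[arrays["rec_input"]]
    labeled_per_starter = np.bincount(
        arrays["rec_starter"][record_labeled],
        weights=arrays["rec_n"][record_labeled],
        minlength=len(circuit.starters),
    ).astype(np.int64)
    total_per_starter = arrays["contacts_per_starter"]

    labeled_ids = frozenset(
        inp for inp, lab in zip(circuit.inputs, input_labeled) if lab
    )
    per_starter = {}
    sf = {}
    for (sid, _), s_star, s_tot in zip(circuit.starters, labeled_per_starter, total_per_starter):
        per_starter[sid] = (int(s_star), int(s_tot))
        sf[sid] = float(s_star / s_tot) if s_tot > 0 else 0.0
    n_inputs = len(circuit.inputs)
    return SpreadOutcome(
        labeled_inputs=labeled_ids,
        labeled_contacts_per_starter=per_starter,
        sf_per_starter=sf,
        if_overall=len(labeled_ids) / n_inputs if n_inputs else 0.0,
        convergence_index=len(labeled_ids) / len(circuit.starters),
        U=float(U),
        seed=int(seed),
    )


@dataclass(frozen=True)
class MetricsEstimate:
    """Replicate means and standard errors of SF, IF and the convergence index."""

    sf_mean: float
    sf_se: float
    if_mean: float
    if_se: float
    ci_mean: float
    n_reps: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "sf_mean": self.sf_mean,
            "sf_se": self.sf_se,
            "if_mean": self.if_mean,
            "if_se": self.if_se,
            "ci_mean": self.ci_mean,
            "n_reps": self.n_reps,
            "seed": self.seed,
        }


def estimate_metrics(
    circuit: SyntheticCircuit, U: float, n_reps: int, seed: int
) -> MetricsEstimate:
    """Replicate :func:`simulate_spread` with independent spawned streams.

    Per-replicate SF is the unweighted mean of per-starter SF values.
    Standard errors use the sample SD over replicates divided by
    ``sqrt(n_reps)`` (0 when ``n_reps == 1``).
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps!r}")
    children = np.random.SeedSequence(seed).spawn(n_reps)
    sfs = np.empty(n_reps)
    ifs = np.empty(n_reps)
    cis = np.empty(n_reps)
    for k, child in enumerate(children):
        rep_seed = int(child.generate_state(1)[0])
        out = simulate_spread(circuit, U, rep_seed)
        sfs[k] = float(np.mean(list(out.sf_per_starter.values())))
        ifs[k] = out.if_overall
        cis[k] = out.convergence_index
    def se(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / math.sqrt(n_reps)) if n_reps > 1 else 0.0
    return MetricsEstimate(
        sf_mean=float(sfs.mean()),
        sf_se=se(sfs),
        if_mean=float(ifs.mean()),
        if_se=se(ifs),
        ci_mean=float(cis.mean()),
        n_reps=int(n_reps),
        seed=int(seed),
    )


def write_circuit_tsv(circuit: SyntheticCircuit, contacts_path, starters_path=None) -> None:
    """Write the contact edge list as TSV (and optionally starter positions)."""
    with open(contacts_path, "w") as fh:
        fh.write("input_id\tstarter_id\tn_contacts\n")
        for inp, st, n in circuit.contacts:
            fh.write(f"{inp}\t{st}\t{n}\n")
    if starters_path is not None:
        write_starters_csv(circuit.starters, starters_path)


def write_starters_csv(starters, path) -> None:
    with open(path, "w") as fh:
        fh.write("id,x_um,y_um,z_um\n")
        for sid, (x, y, z) in starters:
            fh.write(f"{sid},{x},{y},{z}\n")


def read_starters_csv(path) -> List[Tuple[str, Tuple[float, float, float]]]:
    df = pd.read_csv(path, dtype={"id": str})
    return [
        (row.id, (float(row.x_um), float(row.y_um), float(row.z_um)))
        for row in df.itertuples(index=False)
    ]


def read_circuit_tsv(contacts_path, starters_path=None) -> SyntheticCircuit:
    """Read a circuit from the TSV edge list written by :func:`write_circuit_tsv`.

    Without a starter-position CSV, starters found in the edge list are
    placed at the origin.
    """
    df = pd.read_csv(contacts_path, sep="\t", dtype={"input_id": str, "starter_id": str})
    contacts = [
        (row.input_id, row.starter_id, int(row.n_contacts))
        for row in df.itertuples(index=False)
    ]
    inputs = list(dict.fromkeys(inp for inp, _, _ in contacts))
    if starters_path is not None:
        starters = read_starters_csv(starters_path)
    else:
        seen = dict.fromkeys(st for _, st, _ in contacts)
        starters = [(sid, (0.0, 0.0, 0.0)) for sid in seen]
    return SyntheticCircuit(starters=starters, inputs=inputs, contacts=contacts)
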