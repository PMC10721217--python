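"""Seeded generators for circuits and measurement-style datasets.

Everything downstream (the circuit simulator, the colocalization
quantification, the statistics) is exercised on data produced here, so the
generators are first-class, deterministic functions of their spec: same spec
and seed give bit-identical output.

Circuits: each starter receives a fixed number of input connections with
multiplicities drawn from a discrete mix; for each ordered starter pair a
distance-dependent fraction of the subject's inputs is rewired to also
contact the neighbor (pairwise, independent across pairs).

Puncta tables: per dendritic segment, a postsynaptic punctum count is drawn
from a Poisson and the apposed count binomially from the group's true
fraction, with optional beta-distributed per-neuron overdispersion so that
group SEMs — not just means — are matchable to measured summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .circuit_sim import SyntheticCircuit
from .spread_model import MultiplicityMix

__all__ = [
    "SharingBin",
    "CircuitSpec",
    "PunctaGroup",
    "PunctaSpec",
    "generate_circuit",
    "generate_puncta_table",
    "generate_puncta_points",
    "write_puncta_csv",
    "read_puncta_csv",
    "write_points_csv",
    "read_points_csv",
    "EM_MULTIPLICITY_MIX",
    "DEFAULT_SHARING_PROFILE",
]

#: Multiplicity mix dominated by single-contact connections, calibrated to
#: EM-derived connection statistics (~8% multi-contact, ~1.3% with 3+;
#: mean 1.093, close to the measured 1.0965).
EM_MULTIPLICITY_MIX = MultiplicityMix([(1, 0.92), (2, 0.067), (3, 0.013)])


@dataclass(frozen=True)
class SharingBin:
    """Distance band with the pairwise shared-input fraction for starters in it."""

    r_min_um: float
    r_max_um: float
    shared_fraction: float

    def __post_init__(self) -> None:
        if not (0 <= self.r_min_um < self.r_max_um):
            raise ValueError(
                f"require 0 <= r_min_um < r_max_um, got "
                f"[{self.r_min_um!r}, {self.r_max_um!r})"
            )
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError(
                f"shared_fraction must lie in [0, 1], got {self.shared_fraction!r}"
            )


#: Pairwise shared-input fraction vs. inter-starter distance for layer-4
#: cortical neurons (EM-derived): 5% within 50 um, 3.3% at 50-100 um,
#: 1% at 100-200 um, ~0.1% beyond.
DEFAULT_SHARING_PROFILE: Tuple[SharingBin, ...] = (
    SharingBin(0.0, 50.0, 0.05),
    SharingBin(50.0, 100.0, 0.033),
    SharingBin(100.0, 200.0, 0.01),
    SharingBin(200.0, 1e9, 0.001),
)


@dataclass(frozen=True)
class CircuitSpec:
    """Specification of a synthetic starter/input circuit.

    Either ``starter_positions`` (explicit (x, y, z) in um) or ``field_um``
    (side of a cube over which starters are placed uniformly) must be given.
    """

    n_starters: int
    inputs_per_starter: int
    multiplicity_mix: MultiplicityMix
    seed: int
    starter_positions: Optional[Tuple[Tuple[float, float, float], ...]] = None
    field_um: Optional[float] = None
    sharing_profile: Tuple[SharingBin, ...] = ()

    def __post_init__(self) -> None:
        if self.n_starters < 1:
            raise ValueError(f"n_starters must be >= 1, got {self.n_starters!r}")
        if self.inputs_per_starter < 1:
            raise ValueError(
                f"inputs_per_starter must be >= 1, got {self.inputs_per_starter!r}"
            )
        if self.starter_positions is not None:
            positions = tuple(tuple(float(c) for c in p) for p in self.starter_positions)
            if len(positions) != self.n_starters:
                raise ValueError(
                    f"got {len(positions)} starter positions for "
                    f"{self.n_starters} starters"
                )
            object.__setattr__(self, "starter_positions", positions)
        elif self.field_um is None:
            if self.n_starters == 1:
                object.__setattr__(self, "starter_positions", ((0.0, 0.0, 0.0),))
            else:
                raise ValueError(
                    "either starter_positions or field_um must be provided "
                    "for multi-starter circuits"
                )
        elif self.field_um <= 0:
            raise ValueError(f"field_um must be positive, got {self.field_um!r}")
        object.__setattr__(self, "sharing_profile", tuple(self.sharing_profile))


def _shared_fraction_at(profile: Sequence[SharingBin], distance_um: float) -> float:
    for b in profile:
        if b.r_min_um <= distance_um < b.r_max_um:
            return b.shared_fraction
    return 0.0


def generate_circuit(spec: CircuitSpec) -> SyntheticCircuit:
    """Realize a circuit from its spec; deterministic given ``spec.seed``.

    Each starter gets ``inputs_per_starter`` private input neurons with
    multiplicities drawn from ``multiplicity_mix``.  Then, for every ordered
    starter pair (subject, neighbor), a fraction ``s(d)`` of the subject's
    inputs — ``d`` the inter-soma distance, ``s`` piecewise-constant from the
    sharing profile — is rewired to also contact the neighbor.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.starter_positions is not None:
        positions = np.asarray(spec.starter_positions, dtype=float)
    else:
        positions = rng.uniform(0.0, spec.field_um, size=(spec.n_starters, 3))
    starters = [
        (f"s{k}", (float(x), float(y), float(z)))
        for k, (x, y, z) in enumerate(positions)
    ]

    ms = np.array([m for m, _ in spec.multiplicity_mix.entries])
    fs = np.array([f for _, f in spec.multiplicity_mix.entries])
    fs = fs / fs.sum()  # renormalize away the 1e-9 slack

    inputs: List[str] = []
    contacts: List[Tuple[str, str, int]] = []
    owner: List[List[int]] = []  # per starter, indices into `inputs`
    for k, (sid, _) in enumerate(starters):
        mult = rng.choice(ms, size=spec.inputs_per_starter, p=fs)
        idx0 = len(inputs)
        for j, m in enumerate(mult):
            iid = f"i{idx0 + j}"
            inputs.append(iid)
            contacts.append((iid, sid, int(m)))
        owner.append(list(range(idx0, idx0 + spec.inputs_per_starter)))

    if spec.sharing_profile and spec.n_starters > 1:
        existing = {(inp, st) for inp, st, _ in contacts}
        for k, (sid_k, pos_k) in enumerate(starters):
            for j, (sid_j, pos_j) in enumerate(starters):
                if j == k:
                    continue
                d = float(np.linalg.norm(np.subtract(pos_k, pos_j)))
                s = _shared_fraction_at(spec.sharing_profile, d)
                if s <= 0:
                    continue
                share_mask = rng.random(len(owner[k])) < s
                shared_mult = rng.choice(ms, size=int(share_mask.sum()), p=fs)
                for idx, m in zip(np.array(owner[k])[share_mask], shared_mult):
                    pair = (inputs[idx], sid_j)
                    if pair not in existing:
                        contacts.append((pair[0], pair[1], int(m)))
                        existing.add(pair)
    return SyntheticCircuit(starters=starters, inputs=inputs, contacts=contacts)


@dataclass(frozen=True)
class PunctaGroup:
    """One experimental group in a synthetic puncta-count table."""

    label: str
    n_neurons: int
    segments_per_neuron: int
    psd_per_segment_mean: float
    true_apposed_fraction: float
    compartment: str = "unspecified"
    #: Beta concentration of per-neuron fraction variability; ``None`` for
    #: pure binomial sampling (no overdispersion).
    concentration: Optional[float] = 30.0

    def __post_init__(self) -> None:
        if self.n_neurons < 1 or self.segments_per_neuron < 1:
            raise ValueError("n_neurons and segments_per_neuron must be >= 1")
        if self.psd_per_segment_mean <= 0:
            raise ValueError(
                f"psd_per_segment_mean must be positive, got {self.psd_per_segment_mean!r}"
            )
        if not (0.0 <= self.true_apposed_fraction <= 1.0):
            raise ValueError(
                f"true_apposed_fraction must lie in [0, 1], "
                f"got {self.true_apposed_fraction!r}"
            )
        if self.concentration is not None and self.concentration <= 0:
            raise ValueError(f"concentration must be positive, got {self.concentration!r}")


@dataclass(frozen=True)
class PunctaSpec:
    groups: Tuple[PunctaGroup, ...]
    seed: int
    n_animals: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if not self.groups:
            raise ValueError("PunctaSpec requires at least one group")
        if self.n_animals < 1:
            raise ValueError(f"n_animals must be >= 1, got {self.n_animals!r}")


PUNCTA_COLUMNS = [
    "neuron_id", "animal_id", "group", "compartment", "segment_id", "n_psd", "n_apposed",
]


def generate_puncta_table(spec: PunctaSpec) -> pd.DataFrame:
    """Per-segment postsynaptic and apposed punctum counts for every group.

    Per neuron, a true fraction is drawn from
    ``Beta(f*c, (1-f)*c)`` (or taken as ``f`` exactly when ``concentration``
    is ``None`` or ``f`` is 0 or 1); per segment ``n_psd ~ Poisson(mean)``
    and ``n_apposed ~ Binomial(n_psd, fraction)``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    neuron_counter = 0
    for group in spec.groups:
        for n_idx in range(group.n_neurons):
            neuron_id = f"n{neuron_counter}"
            animal_id = f"a{n_idx % spec.n_animals}"
            neuron_counter += 1
            f = group.true_apposed_fraction
            if group.concentration is None or f in (0.0, 1.0):
                frac = f
            else:
                c = group.concentration
                frac = float(rng.beta(f * c, (1.0 - f) * c))
            n_psd = rng.poisson(group.psd_per_segment_mean, size=group.segments_per_neuron)
            n_app = rng.binomial(n_psd, frac)
            for seg, (p, a) in enumerate(zip(n_psd, n_app)):
                rows.append(
                    (neuron_id, animal_id, group.label, group.compartment,
                     f"seg{seg}", int(p), int(a))
                )
    return pd.DataFrame(rows, columns=PUNCTA_COLUMNS)


def generate_puncta_points(
    segment_length_um: float,
    psd_density_per_um: float,
    apposed_fraction: float,
    jitter_xy_um: float,
    jitter_z_um: float,
    seed: int,
    *,
    n_distractors: int = 0,
    distractor_offset_um: float = 2.0,
) -> Tuple[np.ndarray, np.ndarray, List[Tuple[int, int]]]:
    """Point sets for the geometric apposition detector, with ground truth.

    Postsynaptic points are placed along a straight dendrite on the x axis
    (count ~ Poisson(length * density)).  For a fraction of them a partner
    presynaptic point is planted inside the jitter ellipsoid (uniform lateral
    offset up to ``jitter_xy_um``, axial up to ``jitter_z_um``); optional
    distractor presynaptic points are offset laterally by
    ``distractor_offset_um``.  Returns ``(psd_points, syn_points, matching)``
    where ``matching`` lists planted ``(psd_index, syn_index)`` pairs.
    """
    if psd_density_per_um <= 0 or segment_length_um <= 0:
        raise ValueError("segment length and density must be positive")
    if not (0.0 <= apposed_fraction <= 1.0):
        raise ValueError(f"apposed_fraction must lie in [0, 1], got {apposed_fraction!r}")
    if jitter_xy_um < 0 or jitter_z_um < 0:
        raise ValueError("jitters must be >= 0")
    rng = np.random.default_rng(seed)
    n_psd = int(rng.poisson(segment_length_um * psd_density_per_um))
    psd = np.zeros((n_psd, 3))
    psd[:, 0] = rng.uniform(0.0, segment_length_um, size=n_psd)

    syn_rows = []
    matching: List[Tuple[int, int]] = []
    paired = rng.random(n_psd) < apposed_fraction
    for i in np.flatnonzero(paired):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        r = jitter_xy_um * math.sqrt(rng.random())
        dz = rng.uniform(-jitter_z_um, jitter_z_um)
        point = psd[i] + np.array([r * math.cos(theta), r * math.sin(theta), dz])
        matching.append((int(i), len(syn_rows)))
        syn_rows.append(point)
    for _ in range(n_distractors):
        x = rng.uniform(0.0, segment_length_um)
        syn_rows.append(np.array([x, distractor_offset_um, 0.0]))
    syn = np.array(syn_rows) if syn_rows else np.empty((0, 3))
    return psd, syn, matching


def write_puncta_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, columns=PUNCTA_COLUMNS)


def read_puncta_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"neuron_id": str, "animal_id": str, "segment_id": str})
    missing = [c for c in PUNCTA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"puncta CSV missing columns: {missing}")
    return df


def write_points_csv(psd_points: np.ndarray, syn_points: np.ndarray, path) -> None:
    """Write both channels to one CSV with columns ``x_um,y_um,z_um,channel``."""
    with open(path, "w") as fh:
        fh.write("x_um,y_um,z_um,channel\n")
        for x, y, z in np.atleast_2d(psd_points) if len(psd_points) else []:
            fh.write(f"{x},{y},{z},psd\n")
        for x, y, z in np.atleast_2d(syn_points) if len(syn_points) else []:
            fh.write(f"{x},{y},{z},syn\n")


def read_points_csv(path) -> Tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    psd = df[df["channel"] == "psd"][["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    syn = df[df["channel"] == "syn"][["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    return psd, syn
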