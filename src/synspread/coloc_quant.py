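"""Quantification of puncta colocalization and the group statistics built on it.

A postsynaptic punctum counts as apposed when a presynaptic punctum lies
within an anisotropic ellipsoid around it — lateral and axial tolerances are
separate because optical resolution differs between the two directions.  The
statistical unit is the neuron: its fraction pools all of its segments, and
group means/SEMs are computed over neurons.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "AppositionResult",
    "GroupSummary",
    "detect_appositions",
    "colocalization_summary",
    "background_corrected_sf",
    "rank_sum_test",
    "validate_puncta_table",
]

#: Default matching tolerances (um) from lateral/axial optical resolution limits.
DEFAULT_LATERAL_TOL_UM = 0.12
DEFAULT_AXIAL_TOL_UM = 0.35


@dataclass(frozen=True)
class AppositionResult:
    """One-to-one matching between postsynaptic and presynaptic points."""

    pairs: Tuple[Tuple[int, int], ...]  # (psd_index, syn_index)
    apposed: np.ndarray  # bool per psd point

    @property
    def n_apposed(self) -> int:
        return int(self.apposed.sum())


def detect_appositions(
    psd_points,
    syn_points,
    lateral_tol_um: float = DEFAULT_LATERAL_TOL_UM,
    axial_tol_um: float = DEFAULT_AXIAL_TOL_UM,
) -> AppositionResult:
    """Match presynaptic to postsynaptic points inside an anisotropic ellipsoid.

    A candidate pair qualifies when
    ``(dx**2 + dy**2) / lateral_tol**2 + dz**2 / axial_tol**2 <= 1``.
    Matching is one-to-one and greedy by ascending normalized distance, with
    deterministic tie-breaking by (distance, psd index, syn index).
    """
    if lateral_tol_um <= 0 or axial_tol_um <= 0:
        raise ValueError(
            f"tolerances must be positive, got lateral={lateral_tol_um!r}, "
            f"axial={axial_tol_um!r}"
        )
    psd = np.atleast_2d(np.asarray(psd_points, dtype=float))
    syn = np.atleast_2d(np.asarray(syn_points, dtype=float))
    if psd.size == 0:
        return AppositionResult(pairs=(), apposed=np.zeros(0, dtype=bool))
    if not np.all(np.isfinite(psd)) or (syn.size and not np.all(np.isfinite(syn))):
        raise ValueError("point coordinates must be finite")
    apposed = np.zeros(len(psd), dtype=bool)
    if syn.size == 0:
        return AppositionResult(pairs=(), apposed=apposed)

    scale = np.array([lateral_tol_um, lateral_tol_um, axial_tol_um])
    psd_scaled = psd / scale
    syn_scaled = syn / scale
    tree = cKDTree(syn_scaled)
    candidates: List[Tuple[float, int, int]] = []
    for i, neighbors in enumerate(tree.query_ball_point(psd_scaled, r=1.0)):
        for j in neighbors:
            d = float(np.linalg.norm(psd_scaled[i] - syn_scaled[j]))
            candidates.append((d, i, j))
    candidates.sort()

    used_syn = set()
    pairs: List[Tuple[int, int]] = []
    for d, i, j in candidates:
        if apposed[i] or j in used_syn:
            continue
        apposed[i] = True
        used_syn.add(j)
        pairs.append((i, j))
    return AppositionResult(pairs=tuple(pairs), apposed=apposed)


@dataclass(frozen=True)
class GroupSummary:
    """Per-neuron colocalization fractions summarized over one group."""

    group: Tuple
    per_neuron_fraction: Dict[str, float]
    mean_pct: float
    sem_pct: float
    n_neurons: int
    n_animals: int

    def to_dict(self) -> dict:
        return {
            "group": list(self.group),
            "per_neuron_fraction": dict(self.per_neuron_fraction),
            "mean_pct": self.mean_pct,
            "sem_pct": self.sem_pct,
            "n_neurons": self.n_neurons,
            "n_animals": self.n_animals,
        }


def validate_puncta_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"neuron_id", "animal_id", "group", "compartment",
                "segment_id", "n_psd", "n_apposed"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"puncta table missing columns: {sorted(missing)}")
    bad = table["n_apposed"] > table["n_psd"]
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} row(s) have n_apposed > n_psd "
            f"(first offending neuron: {table.loc[bad, 'neuron_id'].iloc[0]!r})"
        )
    if (table["n_psd"] < 0).any() or (table["n_apposed"] < 0).any():
        raise ValueError("counts must be non-negative")
    return table


def colocalization_summary(
    table: pd.DataFrame, group_by: Sequence[str] = ("group",)
) -> List[GroupSummary]:
    """Mean and SEM of per-neuron colocalization fractions for each group.

    Per-neuron fraction = sum(n_apposed) / sum(n_psd) over the neuron's rows
    within the group (segment partitioning therefore does not matter).  The
    SEM uses sample SD (ddof=1) over sqrt(n_neurons); neurons with zero
    postsynaptic puncta are excluded with a logged warning.
    """
    validate_puncta_table(table)
    group_by = list(group_by)
    summaries: List[GroupSummary] = []
    for key, sub in table.groupby(group_by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        per_neuron = sub.groupby("neuron_id", sort=True)[["n_psd", "n_apposed"]].sum()
        empty = per_neuron[per_neuron["n_psd"] == 0]
        if len(empty):
            logger.warning(
                "excluding %d neuron(s) with zero postsynaptic puncta in group %s: %s",
                len(empty), key, list(empty.index),
            )
            per_neuron = per_neuron[per_neuron["n_psd"] > 0]
        if per_neuron.empty:
            continue
        fractions = (per_neuron["n_apposed"] / per_neuron["n_psd"]).astype(float)
        n = len(fractions)
        sem = float(fractions.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        n_animals = sub[sub["neuron_id"].isin(fractions.index)]["animal_id"].nunique()
        summaries.append(
            GroupSummary(
                group=tuple(key),
                per_neuron_fraction=fractions.to_dict(),
                mean_pct=float(fractions.mean() * 100.0),
                sem_pct=sem * 100.0,
                n_neurons=n,
                n_animals=int(n_animals),
            )
        )
    return summaries


def background_corrected_sf(mean_with_pct: float, mean_without_pct: float) -> float:
    """Background-corrected synaptic fraction from two group mean percentages.

    Subtracts the no-trans-complementation (background) colocalization mean
    from the trans-complemented mean, returning a fraction.  Negative
    differences are clamped to 0 with a warning.
    """
    for name, v in (("mean_with_pct", mean_with_pct), ("mean_without_pct", mean_without_pct)):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"{name} must lie in [0, 100], got {v!r}")
    sf = (mean_with_pct - mean_without_pct) / 100.0
    if sf < 0:
        warnings.warn(
            f"background mean ({mean_without_pct}%) exceeds signal mean "
            f"({mean_with_pct}%); clamping SF to 0",
            stacklevel=2,
        )
        return 0.0
    return sf


def rank_sum_test(sample_a, sample_b) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Uses the exact null distribution when the combined sample size is <= 20
    and there are no ties; otherwise a normal approximation with tie and
    continuity corrections.  Returns ``(W, p)`` where ``W`` is the rank sum
    of ``sample_a``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    # convert the Mann-Whitney U of sample a to its rank sum
    W = float(res.statistic + a.size * (a.size + 1) / 2.0)
    p = float(res.pvalue)
    if res.statistic == a.size * b.size / 2.0:
        # statistic exactly at the null center: two-sided p is 1 by
        # definition (the continuity correction would otherwise push it below)
        p = 1.0
    return W, p
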