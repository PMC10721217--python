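"""Distance-binned correction for labeling caused by inputs shared between starters.

An input neuron that contacts two starter cells can have its terminals onto
starter A marked because the tracer spread into it from starter B — no spread
occurred at the observed contact.  The measured synaptic fraction (SF) is
therefore inflated relative to the input fraction (IF).  Each neighboring
starter at distance ``d`` adds, to first order,

    starter_fraction * shared_fraction(d) * IF * (1 - IF)

to the measured SF: a fraction ``shared_fraction`` of the subject's inputs
also contacts the neighbor, each is labeled through the neighbor with
probability IF, and only the ``1 - IF`` not already labeled directly are new
additions.  Summing over neighbors in distance bins yields the total shared
contribution and the implied IF/SF ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import pandas as pd

__all__ = [
    "DistanceBin",
    "CorrectionResult",
    "DEFAULT_PROFILE",
    "default_profile",
    "bin_contribution",
    "correct",
    "combined_if_sf",
    "estimate_if_and_u",
    "fixed_point_if",
    "read_profile_csv",
    "write_profile_csv",
]


def _check_fraction(name: str, value: float) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class DistanceBin:
    """Neighbors and shared-input fraction within a radial distance band.

    ``n_neighbors`` counts candidate starter neurons with somata between
    ``r_min_um`` and ``r_max_um`` from the subject starter; ``shared_fraction``
    is the proportion of the subject's inputs that also contact a neighbor at
    that distance.
    """

    r_min_um: float
    r_max_um: float
    n_neighbors: int
    shared_fraction: float

    def __post_init__(self) -> None:
        if not (0 <= self.r_min_um < self.r_max_um):
            raise ValueError(
                f"require 0 <= r_min_um < r_max_um, got "
                f"[{self.r_min_um!r}, {self.r_max_um!r})"
            )
        if self.n_neighbors < 0 or self.n_neighbors != int(self.n_neighbors):
            raise ValueError(f"n_neighbors must be an integer >= 0, got {self.n_neighbors!r}")
        _check_fraction("shared_fraction", self.shared_fraction)


#: Distance profile for layer-4 cortical starters: neighbor counts from
#: labeled-cell nearest-neighbor statistics, shared fractions from EM-derived
#: pairwise common-input rates.  Bands beyond 200 um (~0.1% shared) are
#: negligible and omitted.
DEFAULT_PROFILE: Tuple[DistanceBin, ...] = (
    DistanceBin(0.0, 50.0, 7, 0.05),
    DistanceBin(50.0, 100.0, 13, 0.033),
    DistanceBin(100.0, 200.0, 28, 0.01),
)


def default_profile() -> List[DistanceBin]:
    return list(DEFAULT_PROFILE)


@dataclass(frozen=True)
class CorrectionResult:
    """Shared-input contributions per bin and the implied IF/SF ratio."""

    per_bin_contribution: Tuple[float, ...]
    total_shared: float
    if_sf_ratio_shared: float
    starter_fraction: float

    def to_dict(self) -> dict:
        return {
            "per_bin_contribution": list(self.per_bin_contribution),
            "total_shared": self.total_shared,
            "if_sf_ratio_shared": self.if_sf_ratio_shared,
            "starter_fraction": self.starter_fraction,
        }


def bin_contribution(
    bin: DistanceBin, IF: float, starter_fraction: float = 1.0, *, compound: bool = False
) -> float:
    """Shared-input contribution of one distance bin to the measured SF.

    Linear (default): ``n * starter_fraction * shared * IF * (1 - IF)`` —
    every neighbor adds the same first-order increment.  With
    ``compound=True`` the per-neighbor increment is compounded,
    ``1 - (1 - starter_fraction*shared*IF*(1-IF))**n``, which is always <=
    the linear sum and converges to it as increments shrink.
    """
    IF = _check_fraction("IF", IF)
    starter_fraction = _check_fraction("starter_fraction", starter_fraction)
    increment = starter_fraction * bin.shared_fraction * IF * (1.0 - IF)
    if compound:
        return 1.0 - (1.0 - increment) ** bin.n_neighbors
    return bin.n_neighbors * increment


def correct(
    profile: Sequence[DistanceBin],
    IF: float,
    starter_fraction: float = 1.0,
    *,
    compound: bool = False,
) -> CorrectionResult:
    """Sum shared-input contributions over a distance profile.

    Bins must be sorted by distance and non-overlapping.  The total is
    clipped to [0, 1]; ``if_sf_ratio_shared`` is ``1 - total``.
    """
    IF = _check_fraction("IF", IF)
    starter_fraction = _check_fraction("starter_fraction", starter_fraction)
    for prev, cur in zip(profile, profile[1:]):
        if cur.r_min_um < prev.r_max_um:
            raise ValueError(
                f"distance bins overlap or are unsorted: "
                f"[{prev.r_min_um}, {prev.r_max_um}) then [{cur.r_min_um}, {cur.r_max_um})"
            )
    contributions = tuple(
        bin_contribution(b, IF, starter_fraction, compound=compound) for b in profile
    )
    total = min(max(sum(contributions), 0.0), 1.0)
    return CorrectionResult(
        per_bin_contribution=contributions,
        total_shared=total,
        if_sf_ratio_shared=1.0 - total,
        starter_fraction=starter_fraction,
    )


def combined_if_sf(shared_ratio: float, multiplicity_ratio: float) -> float:
    """Combine the shared-input and multiplicity IF/SF ratios (product)."""
    for name, value in (("shared_ratio", shared_ratio),
                        ("multiplicity_ratio", multiplicity_ratio)):
        if not (0.0 < value <= 1.0):
            raise ValueError(f"{name} must lie in (0, 1], got {value!r}")
    return shared_ratio * multiplicity_ratio


def estimate_if_and_u(
    SF_measured: float,
    combined_ratio: float,
    multiplicity_inflation: float = 1.08,
    *,
    round_if_decimals: int | None = None,
) -> Tuple[float, float]:
    """Estimate the input fraction and unitary efficiency from measured SF.

    ``IF = SF_measured * combined_ratio``; multiple contacts per connection
    make IF larger than U by ``multiplicity_inflation`` (default 1.08), so
    ``U = IF / multiplicity_inflation``.  Set ``round_if_decimals`` to round
    IF before the division (the headline numbers round IF to one decimal
    first).
    """
    if not (0.0 < SF_measured < 1.0):
        raise ValueError(f"SF_measured must lie strictly in (0, 1), got {SF_measured!r}")
    if not (0.0 < combined_ratio <= 1.0):
        raise ValueError(f"combined_ratio must lie in (0, 1], got {combined_ratio!r}")
    if multiplicity_inflation < 1.0:
        raise ValueError(
            f"multiplicity_inflation must be >= 1, got {multiplicity_inflation!r}"
        )
    IF = SF_measured * combined_ratio
    if round_if_decimals is not None:
        IF = round(IF, round_if_decimals)
    U = IF / multiplicity_inflation
    return IF, U


def fixed_point_if(
    profile: Sequence[DistanceBin],
    SF_measured: float,
    starter_fraction: float = 1.0,
    *,
    multiplicity_ratio: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> Tuple[float, CorrectionResult]:
    """Self-consistent IF: iterate ``IF <- SF * ratio(IF)`` to a fixed point.

    The one-pass correction uses a fixed assumed IF inside the very
    correction that estimates IF.  This flagged extension removes that
    circularity by iterating until ``|dIF| < tol``.  Returns the converged IF
    and the correction evaluated there.
    """
    if not (0.0 < SF_measured < 1.0):
        raise ValueError(f"SF_measured must lie strictly in (0, 1), got {SF_measured!r}")
    IF = SF_measured
    for _ in range(max_iter):
        res = correct(profile, IF, starter_fraction)
        IF_next = SF_measured * res.if_sf_ratio_shared * multiplicity_ratio
        if abs(IF_next - IF) < tol:
            return IF_next, correct(profile, IF_next, starter_fraction)
        IF = IF_next
    raise RuntimeError(f"fixed-point iteration did not converge in {max_iter} steps")


_PROFILE_COLUMNS = ["r_min_um", "r_max_um", "n_neighbors", "shared_fraction"]


def read_profile_csv(path) -> List[DistanceBin]:
    """Read a distance profile from a CSV with columns
    ``r_min_um,r_max_um,n_neighbors,shared_fraction``."""
    df = pd.read_csv(path)
    missing = [c for c in _PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile CSV missing columns: {missing}")
    return [
        DistanceBin(
            r_min_um=float(row.r_min_um),
            r_max_um=float(row.r_max_um),
            n_neighbors=int(row.n_neighbors),
            shared_fraction=float(row.shared_fraction),
        )
        for row in df.itertuples(index=False)
    ]


def write_profile_csv(profile: Iterable[DistanceBin], path) -> None:
    pd.DataFrame(
        [
            {
                "r_min_um": b.r_min_um,
                "r_max_um": b.r_max_um,
                "n_neighbors": b.n_neighbors,
                "shared_fraction": b.shared_fraction,
            }
            for b in profile
        ],
        columns=_PROFILE_COLUMNS,
    ).to_csv(path, index=False)
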