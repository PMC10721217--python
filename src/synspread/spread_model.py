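"""Closed-form model linking per-contact spread efficiency to labeling fractions.

The model describes a starter neuron receiving synaptic contacts from input
neurons.  Each input neuron makes ``M`` contacts (its *multiplicity*) and a
tracer crosses each contact independently with probability ``U`` (the
*unitary synaptic efficiency*).  An input neuron is labeled if the tracer
crosses at least one of its contacts; once labeled, all of its contacts are
presynaptically marked.  Two observable fractions follow:

* ``IF`` (*input fraction*): proportion of input neurons labeled.
* ``SF`` (*synaptic fraction*): proportion of synaptic contacts labeled.

For the canonical two-population case (``Na``/``Nb`` inputs with
multiplicities ``Ma``/``Mb`` and ratio ``R = Na/Nb``):

.. math::

    p_x = 1 - (1 - U)^{M_x}

    IF = \\frac{R\\,p_a + p_b}{R + 1}, \\qquad
    SF = \\frac{R\\,p_a M_a + p_b M_b}{R\\,M_a + M_b}

``SF >= IF`` always, with equality when ``Ma == Mb`` or ``U`` is 0 or 1.
:func:`evaluate_mixture` generalizes to an arbitrary discrete multiplicity
distribution; the two-population form stays canonical for all headline
numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

import pandas as pd

__all__ = [
    "TwoPopulationModel",
    "MultiplicityMix",
    "ModelEvaluation",
    "labeling_probability",
    "evaluate",
    "evaluate_mixture",
    "solve_unitary_efficiency",
    "minimize_if_sf_over_R",
    "sweep_curves",
    "write_sweep_csv",
]

_FRACTION_SUM_TOL = 1e-9


def _check_probability(name: str, value: float) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return value


def _check_multiplicity(name: str, value: int) -> int:
    if value != int(value) or value < 1:
        raise ValueError(f"{name} must be an integer >= 1, got {value!r}")
    return int(value)


@dataclass(frozen=True)
class TwoPopulationModel:
    """Two input populations with multiplicities ``Ma``/``Mb`` in ratio ``R``.

    Parameters
    ----------
    R : float
        Ratio of population-a to population-b input neuron counts (> 0).
    Ma, Mb : int
        Synaptic contacts per input neuron in each population (>= 1).
    U : float
        Probability of tracer spread across one contact, in [0, 1].
    """

    R: float
    Ma: int
    Mb: int
    U: float

    def __post_init__(self) -> None:
        if not (self.R > 0 and math.isfinite(self.R)):
            raise ValueError(f"R must be positive and finite, got {self.R!r}")
        _check_multiplicity("Ma", self.Ma)
        _check_multiplicity("Mb", self.Mb)
        _check_probability("U", self.U)


@dataclass(frozen=True)
class MultiplicityMix:
    """Discrete distribution of synaptic contacts per input connection.

    ``entries`` is a sequence of ``(M, f)`` pairs: a fraction ``f`` of input
    neurons each make ``M`` contacts.  Fractions must sum to 1.
    """

    entries: Tuple[Tuple[int, float], ...]

    def __init__(self, entries: Iterable[Tuple[int, float]]) -> None:
        entries = tuple((int(m), float(f)) for m, f in entries)
        if not entries:
            raise ValueError("MultiplicityMix entries must be non-empty")
        for m, f in entries:
            _check_multiplicity("M", m)
            if f < 0:
                raise ValueError(f"fraction for M={m} must be >= 0, got {f!r}")
        ms = [m for m, _ in entries]
        if len(set(ms)) != len(ms):
            raise ValueError(f"M values must be distinct, got {ms}")
        total = sum(f for _, f in entries)
        if abs(total - 1.0) > _FRACTION_SUM_TOL:
            raise ValueError(f"fractions must sum to 1 (got {total!r})")
        object.__setattr__(self, "entries", entries)

    @property
    def mean_multiplicity(self) -> float:
        return sum(m * f for m, f in self.entries)

    @classmethod
    def from_two_populations(cls, R: float, Ma: int, Mb: int) -> "MultiplicityMix":
        """Mix with fractions ``R/(R+1)`` at ``Ma`` and ``1/(R+1)`` at ``Mb``."""
        if not (R > 0 and math.isfinite(R)):
            raise ValueError(f"R must be positive and finite, got {R!r}")
        if Ma == Mb:
            return cls([(Ma, 1.0)])
        return cls([(Ma, R / (R + 1.0)), (Mb, 1.0 / (R + 1.0))])


@dataclass(frozen=True)
class ModelEvaluation:
    """Labeling fractions implied by a model at a given efficiency.

    ``ratio`` is ``IF / SF``, defined as 1 when ``SF == 0`` (the ``U -> 0``
    limit of the equal-multiplicity case; keeps sweep tables total).
    ``pa``/``pb`` are the per-neuron labeling probabilities of the two
    populations; ``None`` when the evaluation came from a mixture with a
    different number of components.
    """

    IF: float
    SF: float
    ratio: float
    pa: float | None = None
    pb: float | None = None


def labeling_probability(U: float, M: int) -> float:
    """Probability that an input neuron with ``M`` contacts is labeled.

    Each contact is crossed independently with probability ``U``, so the
    neuron is labeled with probability ``1 - (1 - U)**M``.

    Examples
    --------
    >>> labeling_probability(0.28, 1)
    0.28
    >>> round(labeling_probability(0.28, 2), 4)
    0.4816
    """
    U = _check_probability("U", U)
    M = _check_multiplicity("M", M)
    return 1.0 - (1.0 - U) ** M


def evaluate(model: TwoPopulationModel) -> ModelEvaluation:
    """Evaluate ``IF``, ``SF`` and their ratio for a two-population model."""
    pa = labeling_probability(model.U, model.Ma)
    pb = labeling_probability(model.U, model.Mb)
    IF = (model.R * pa + pb) / (model.R + 1.0)
    SF = (model.R * pa * model.Ma + pb * model.Mb) / (model.Ma * model.R + model.Mb)
    ratio = IF / SF if SF > 0 else 1.0
    return ModelEvaluation(IF=IF, SF=SF, ratio=ratio, pa=pa, pb=pb)


def evaluate_mixture(mix: MultiplicityMix, U: float) -> ModelEvaluation:
    """Evaluate labeling fractions under an arbitrary multiplicity mix.

    ``IF = sum_k f_k p_k`` and ``SF = sum_k f_k M_k p_k / sum_k f_k M_k``
    with ``p_k = 1 - (1 - U)**M_k``.  Reduces exactly to :func:`evaluate`
    when the mix has two components in ratio ``R``.
    """
    U = _check_probability("U", U)
    probs = [(m, f, labeling_probability(U, m)) for m, f in mix.entries]
    IF = sum(f * p for _, f, p in probs)
    mean_m = mix.mean_multiplicity
    SF = sum(f * m * p for m, f, p in probs) / mean_m
    ratio = IF / SF if SF > 0 else 1.0
    if len(probs) == 2:
        pa, pb = probs[0][2], probs[1][2]
    elif len(probs) == 1:
        pa = pb = probs[0][2]
    else:
        pa = pb = None
    return ModelEvaluation(IF=IF, SF=SF, ratio=ratio, pa=pa, pb=pb)


def solve_unitary_efficiency(
    SF_target: float, R: float, Ma: int, Mb: int, *, tol: float = 1e-9
) -> float:
    """Invert the ``SF`` formula for ``U`` by bisection.

    ``SF`` is strictly increasing in ``U`` on [0, 1] with ``SF(0) = 0`` and
    ``SF(1) = 1``, so the root is unique.  Bisection is used for robustness;
    the returned ``U`` satisfies ``|SF(U) - SF_target| <= tol``.
    """
    SF_target = float(SF_target)
    if not (0.0 < SF_target < 1.0):
        raise ValueError(f"SF_target must lie strictly in (0, 1), got {SF_target!r}")

    def sf(u: float) -> float:
        return evaluate(TwoPopulationModel(R=R, Ma=Ma, Mb=Mb, U=u)).SF

    lo, hi = 0.0, 1.0
    while hi - lo > 1e-15:
        mid = 0.5 * (lo + hi)
        val = sf(mid)
        if abs(val - SF_target) <= tol and hi - lo < 1e-9:
            return mid
        if val < SF_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def minimize_if_sf_over_R(
    U: float,
    Ma: int,
    Mb: int,
    R_min: float,
    R_max: float,
    *,
    n_grid: int = 256,
    rel_tol: float = 1e-9,
) -> Tuple[float, float]:
    """Minimize ``IF/SF`` over ``R`` in ``[R_min, R_max]``.

    A coarse log-spaced grid scan locates the basin (the minimum is shallow),
    then golden-section search refines it.  Returns ``(R_star, ratio_star)``.
    """
    if not (0 < R_min < R_max):
        raise ValueError(
            f"require 0 < R_min < R_max, got R_min={R_min!r}, R_max={R_max!r}"
        )
    _check_probability("U", U)

    def ratio_at(logR: float) -> float:
        return evaluate(TwoPopulationModel(R=math.exp(logR), Ma=Ma, Mb=Mb, U=U)).ratio

    lo, hi = math.log(R_min), math.log(R_max)
    grid = [lo + (hi - lo) * i / (n_grid - 1) for i in range(n_grid)]
    vals = [ratio_at(x) for x in grid]
    k = min(range(n_grid), key=vals.__getitem__)
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, n_grid - 1)]

    # golden-section search on log R
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = ratio_at(c), ratio_at(d)
    while b - a > rel_tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = ratio_at(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = ratio_at(d)
    x_star = 0.5 * (a + b)
    R_star = math.exp(x_star)
    return R_star, ratio_at(x_star)


def sweep_curves(
    U_values: Sequence[float],
    R_grid: Sequence[float],
    Ma: int,
    Mb: int,
) -> pd.DataFrame:
    """Tabulate ``evaluate`` over a grid, one row per ``(U, R)`` pair.

    Returns a dataframe with columns ``U, R, Ma, Mb, SF, IF, ratio`` in
    deterministic grid order (``U`` outer, ``R`` inner).
    """
    if len(U_values) == 0 or len(R_grid) == 0:
        raise ValueError("U_values and R_grid must be non-empty")
    rows = []
    for U in U_values:
        for R in R_grid:
            ev = evaluate(TwoPopulationModel(R=R, Ma=Ma, Mb=Mb, U=U))
            rows.append(
                {"U": U, "R": R, "Ma": Ma, "Mb": Mb,
                 "SF": ev.SF, "IF": ev.IF, "ratio": ev.ratio}
            )
    return pd.DataFrame(rows, columns=["U", "R", "Ma", "Mb", "SF", "IF", "ratio"])


def write_sweep_csv(df: pd.DataFrame, path) -> None:
    """Write a sweep table as CSV, floats at 6 significant digits."""
    df.to_csv(path, index=False, float_format="%.6g")
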