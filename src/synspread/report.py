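"""Desk-scale reproduction of the headline numbers of the source analysis.

Every target is recomputed from scratch through the package's public
operations and compared against the reported reference value at its printed
precision.  Two reference values (t7, t8) were read off plotted curves in
the original analysis; exact computation lands one final-digit step away,
which is flagged in the row's note rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

from . import common_input, spread_model
from .coloc_quant import background_corrected_sf

__all__ = ["TargetRow", "compute_targets", "format_report"]

# Measured group means (percent colocalization) with and without
# trans-complementation; these are reported summary inputs, not outputs.
MEAN_WITH_OG_PCT = 50.61
MEAN_WITHOUT_OG_PCT = 8.86

MEASURED_SF = 0.4
ASSUMED_IF = 0.3
MULTIPLICITY_INFLATION = 1.08


@dataclass(frozen=True)
class TargetRow:
    target_id: str
    description: str
    value: float
    n: int
    reference: float
    matches_reference: bool
    note: Optional[str] = None

    def to_dict(self) -> dict:
        d = {
            "id": self.target_id,
            "description": self.description,
            "value": self.value,
            "n": self.n,
            "reference": self.reference,
            "matches_reference": self.matches_reference,
        }
        if self.note:
            d["note"] = self.note
        return d


def compute_targets(starter_fraction: float = 1.0) -> List[TargetRow]:
    """Recompute all desk-scale targets; deterministic (no randomness).

    ``starter_fraction`` scales the shared-input correction (1.0 treats every
    candidate neighbor as a starter); the half-starter scenario t4 always
    uses 0.5 regardless.
    """
    rows: List[TargetRow] = []
    profile = common_input.default_profile()

    # t1 — background-corrected synaptic fraction, integer percent
    sf = background_corrected_sf(MEAN_WITH_OG_PCT, MEAN_WITHOUT_OG_PCT)
    rows.append(TargetRow("t1", "background-corrected SF (%)",
                          round(sf * 100.0), 2, 42, round(sf * 100.0) == 42))

    # t2/t3 — total shared-input proportion and implied IF/SF
    res_full = common_input.correct(profile, ASSUMED_IF, starter_fraction)
    t2 = round(res_full.total_shared, 2)
    rows.append(TargetRow("t2", "total shared-input proportion of SF",
                          t2, len(profile), 0.22, t2 == 0.22))
    t3 = round(res_full.if_sf_ratio_shared, 2)
    rows.append(TargetRow("t3", "IF/SF from shared input (all neighbors starters)",
                          t3, len(profile), 0.78, t3 == 0.78))

    # t4 — half of the candidate neighbors are starters
    res_half = common_input.correct(profile, ASSUMED_IF, 0.5)
    t4 = round(res_half.if_sf_ratio_shared, 2)
    rows.append(TargetRow("t4", "IF/SF from shared input (half starters)",
                          t4, len(profile), 0.89, t4 == 0.89))

    # t5 — 50-100 um bin contribution, integer percent
    mid_bin = profile[1]
    t5 = round(common_input.bin_contribution(mid_bin, ASSUMED_IF, starter_fraction) * 100.0)
    rows.append(TargetRow("t5", "50-100 um shared-input contribution (%)",
                          t5, 1, 9, t5 == 9))

    # t6 — IF/SF of the two-population model at U=0.28, R=2
    ev6 = spread_model.evaluate(spread_model.TwoPopulationModel(R=2, Ma=1, Mb=2, U=0.28))
    t6 = round(ev6.ratio, 2)
    rows.append(TargetRow("t6", "IF/SF at U=0.28, R=2, Ma=1, Mb=2",
                          t6, 1, 0.91, t6 == 0.91))

    # t7 — U solving SF=0.4 at R=10 (reference read from a plotted curve)
    u7 = spread_model.solve_unitary_efficiency(MEASURED_SF, R=10, Ma=1, Mb=2)
    t7 = round(u7, 2)
    rows.append(TargetRow(
        "t7", "U solving SF=0.4 at R=10, Ma=1, Mb=2", t7, 1, 0.35, t7 == 0.35,
        note=f"exact inversion gives U={u7:.4f}; the 0.35 reference was read "
             f"from a plotted curve family",
    ))

    # t8 — IF/SF at U=0.35, R=10 (reference likewise figure-read)
    ev8 = spread_model.evaluate(spread_model.TwoPopulationModel(R=10, Ma=1, Mb=2, U=0.35))
    t8 = round(ev8.ratio, 2)
    rows.append(TargetRow(
        "t8", "IF/SF at U=0.35, R=10, Ma=1, Mb=2", t8, 1, 0.95, t8 == 0.95,
        note=f"exact ratio is {ev8.ratio:.4f} ('about 0.95' in the source)",
    ))

    # t9 — minimum IF/SF over R at U=0.22, Ma=1, Mb=3
    _, ratio_star = spread_model.minimize_if_sf_over_R(0.22, 1, 3, 0.01, 100.0)
    t9 = round(ratio_star, 1)
    rows.append(TargetRow("t9", "min over R of IF/SF at U=0.22, Ma=1, Mb=3",
                          t9, 1, 0.8, t9 == 0.8))

    # t10 — combined IF/SF (shared-input x multiplicity, both at printed precision)
    t10 = round(common_input.combined_if_sf(t3, 0.95), 2)
    rows.append(TargetRow("t10", "combined IF/SF (shared x multiplicity)",
                          t10, 1, 0.74, t10 == 0.74))

    # t11 — IF implied by measured SF and the shared-input ratio, integer percent
    t11 = round(MEASURED_SF * res_full.if_sf_ratio_shared * 100.0)
    rows.append(TargetRow("t11", "IF (%) from SF=0.4 and shared-input ratio",
                          t11, 1, 31, t11 == 31))

    # t12 — U from the combined-correction IF estimate (IF rounded to 0.3 first)
    _, u12 = common_input.estimate_if_and_u(
        MEASURED_SF, 0.74, MULTIPLICITY_INFLATION, round_if_decimals=1
    )
    t12 = round(u12, 2)
    rows.append(TargetRow("t12", "U from IF=0.3 and 1.08 multiplicity inflation",
                          t12, 1, 0.28, t12 == 0.28))
    return rows


def format_report(rows: List[TargetRow]) -> str:
    lines = [f"{'id':<4} {'value':>8} {'ref':>8}  {'ok':<4} description"]
    for r in rows:
        ok = "PASS" if r.matches_reference else "FAIL"
        lines.append(f"{r.target_id:<4} {r.value:>8g} {r.reference:>8g}  {ok:<4} {r.description}")
        if r.note:
            lines.append(f"     note: {r.note}")
    return "\n".join(lines)
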