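"""Risk tables and risk-reducing surgery benefit estimates.

The standard layout has nine age-interval rows — 25-40, 25-50, 25-60, 25-70
(cancers preventable by surgery at 25), 40-70, 50-70, 60-70 (preventable by
surgery at 40/50/60), 40-50 and 50-60 — and, per gene, the conditional
interval risk, the 10-year survival after diagnosis, and the risk of being
diagnosed in the interval and dying of it within 10 years:

    death_risk = interval_risk * (1 - survival_10y).

All arithmetic is on unrounded values; whole-percent rounding (half away from
zero) is applied only at render time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .risk import CumulativeIncidenceCurve, interval_risk
from .survival import CombinedSurvivalParams, combined_survival, ec_fraction

#: Age-interval rows of the published tables, in print order.
TABLE_ROWS: tuple[tuple[int, int], ...] = (
    (25, 40), (25, 50), (25, 60), (25, 70),
    (40, 70), (50, 70), (60, 70),
    (40, 50), (50, 60),
)


@dataclass
class RiskTableRow:
    a: int
    b: int
    risk: float
    survival: float | None  # None when there is no risk to survive (empty cell)
    death_risk: float


@dataclass
class RiskTable:
    """Interval risks, survival and death risks for one gene x endpoint."""

    gene: str
    endpoint: str
    rows: list[RiskTableRow]
    combined_fallback_rows: list[tuple[int, int]] = field(default_factory=list)

    def to_frame(self, rounded: bool = False) -> pd.DataFrame:
        data = []
        for r in self.rows:
            if rounded:
                surv = "" if r.survival is None else round_percent(r.survival)
                data.append({"age_group": f"{r.a} to {r.b} years",
                             "risk": round_percent(r.risk), "survival": surv,
                             "death_risk": round_percent(r.death_risk)})
            else:
                data.append({"age_group": f"{r.a} to {r.b} years", "risk": r.risk,
                             "survival": r.survival, "death_risk": r.death_risk})
        return pd.DataFrame(data)


@dataclass
class BenefitEstimate:
    """Cancers and deaths prevented by risk-reducing surgery at a given age."""

    gene: str
    surgery: str  # hysterectomy | BSO | both
    surgery_age: int
    horizon_age: int
    cancers_prevented: float
    deaths_prevented: float


def round_percent(x: float) -> int:
    """Whole-percent display rounding, half away from zero."""
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"probability out of range: {x}")
    return int(100.0 * x + 0.5)


def death_risk(risk: float, survival10: float) -> float:
    """Risk of diagnosis in the interval and death from it within 10 years."""
    for p in (risk, survival10):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability out of range: {p}")
    return risk * (1.0 - survival10)


def build_gene_table(curve: CumulativeIncidenceCurve, survival10: float) -> RiskTable:
    """Nine-row risk table for one gene x endpoint from its cumulative curve."""
    rows = []
    for a, b in TABLE_ROWS:
        r = interval_risk(curve, a, b).risk
        rows.append(RiskTableRow(a=a, b=b, risk=r, survival=survival10,
                                 death_risk=death_risk(r, survival10)))
    return RiskTable(gene=curve.gene, endpoint=curve.endpoint, rows=rows)


def build_combined_table(
    ec_curve: CumulativeIncidenceCurve,
    oc_curve: CumulativeIncidenceCurve,
    combined_curve: CumulativeIncidenceCurve | None,
    ec_surv: float,
    oc_surv: float,
) -> RiskTable:
    """Combined endometrial-and/or-ovarian table with interpolated survival.

    The endometrial fraction comes from the unrounded endpoint-specific
    interval risks; the combined risk comes from ``combined_curve`` when one
    is available, otherwise from the conservative independence fallback
    1-(1-EC)(1-OC), with the rows so filled recorded on the table.
    """
    gene = ec_curve.gene
    rows = []
    fallback_rows: list[tuple[int, int]] = []
    for a, b in TABLE_ROWS:
        ec_r = interval_risk(ec_curve, a, b).risk
        oc_r = interval_risk(oc_curve, a, b).risk
        if combined_curve is not None:
            comb_r = interval_risk(combined_curve, a, b).risk
        else:
            comb_r = 1.0 - (1.0 - ec_r) * (1.0 - oc_r)
            fallback_rows.append((a, b))
        if ec_r == 0.0 and oc_r == 0.0:
            # no risk in the interval: survival cell is empty in print
            rows.append(RiskTableRow(a=a, b=b, risk=comb_r, survival=None, death_risk=0.0))
            continue
        frac = ec_fraction(ec_r, oc_r)
        surv = combined_survival(
            CombinedSurvivalParams(ec_survival=ec_surv, oc_survival=oc_surv, ec_fraction=frac)
        )
        rows.append(RiskTableRow(a=a, b=b, risk=comb_r, survival=surv,
                                 death_risk=death_risk(comb_r, surv)))
    return RiskTable(gene=gene, endpoint="EC_or_OC", rows=rows,
                     combined_fallback_rows=fallback_rows)


def rrs_benefit(
    curve: CumulativeIncidenceCurve,
    survival10: float,
    surgery_age: int,
    horizon_age: int,
    surgery: str | None = None,
) -> BenefitEstimate:
    """Counterfactual benefit of risk-reducing surgery at ``surgery_age``.

    Cancers prevented before ``horizon_age`` equal the conditional interval
    risk the woman would otherwise face; deaths prevented are those cancers
    times one minus the 10-year survival.
    """
    if not (25 <= surgery_age <= horizon_age <= 75):
        raise ValueError(f"require 25 <= surgery_age <= horizon_age <= 75, "
                         f"got {surgery_age}, {horizon_age}")
    if surgery is None:
        surgery = {"EC": "hysterectomy", "OC": "BSO"}.get(curve.endpoint, "both")
    prevented = interval_risk(curve, surgery_age, horizon_age).risk
    return BenefitEstimate(
        gene=curve.gene,
        surgery=surgery,
        surgery_age=surgery_age,
        horizon_age=horizon_age,
        cancers_prevented=prevented,
        deaths_prevented=death_risk(prevented, survival10),
    )
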