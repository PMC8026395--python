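"""Cumulative and conditional age-interval risks from annual incidence rates.

Cumulative incidence Q is built by the annual recursion

    Q(age) = Q(age-1) + [1 - Q(age-1)] * AIR(age),   Q(25) = 0,

where AIR(age) is the annual incidence rate of the 5-year bin containing the
year [age-1, age), and incidence before 25 is zero. The recursion is
algebraically identical to Q(b) = 1 - prod over years t in [25,b) of
(1 - AIR(t)); both forms are exposed and must agree to floating tolerance.

The conditional risk of a first cancer in [a, b) for a woman cancer-free with
the organ intact at age a is (Q(b) - Q(a)) / (1 - Q(a)).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

from .incidence import BIN_STARTS, BIN_WIDTH, AgeBinIncidence

GRID_MIN = 25
GRID_MAX = 75


@dataclass
class CumulativeIncidenceCurve:
    """Q(age) on the integer age grid 25..75 for one gene x endpoint."""

    gene: str
    endpoint: str
    q: dict[int, float]
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"gene": self.gene, "endpoint": self.endpoint,
             "q": {str(k): v for k, v in self.q.items()}, "warnings": self.warnings},
            indent=2,
        )


@dataclass
class IntervalRisk:
    """Risk of a first cancer in [a, b) given cancer-free, organ intact at a."""

    gene: str
    endpoint: str
    a: int
    b: int
    risk: float


def cumulative_incidence(rates: list[AgeBinIncidence]) -> CumulativeIncidenceCurve:
    """Run the annual recursion over bins 25..70 to build Q on ages 25..75."""
    by_bin = {b.bin_start: b for b in rates}
    missing = [s for s in BIN_STARTS if s not in by_bin]
    if missing:
        raise ValueError(f"missing age bins: {missing}")

    gene = rates[0].gene
    endpoint = rates[0].endpoint
    notes: list[str] = []
    air: dict[int, float] = {}
    for s in BIN_STARTS:
        b = by_bin[s]
        if b.air is None:
            notes.append(f"bin {s}: AIR undefined (no person-years); treated as 0")
            warnings.warn(
                f"{gene}/{endpoint} bin {s}: AIR undefined, treated as 0", stacklevel=2
            )
            air[s] = 0.0
        else:
            air[s] = b.air
            if b.unreliable:
                notes.append(f"bin {s}: flagged unreliable ({b.person_years:.1f} person-years)")

    q: dict[int, float] = {GRID_MIN: 0.0}
    for age in range(GRID_MIN + 1, GRID_MAX + 1):
        year_bin = min(70, 25 + ((age - 1 - 25) // BIN_WIDTH) * BIN_WIDTH)
        h = air[year_bin]
        q[age] = q[age - 1] + (1.0 - q[age - 1]) * h
    return CumulativeIncidenceCurve(gene=gene, endpoint=endpoint, q=q, warnings=notes)


def interval_risk(curve: CumulativeIncidenceCurve, a: int, b: int) -> IntervalRisk:
    """Conditional risk (Q(b) - Q(a)) / (1 - Q(a)) on the integer grid."""
    for age in (a, b):
        if age not in curve.q:
            raise ValueError(f"age {age} is off the curve grid {GRID_MIN}..{GRID_MAX}")
    if a > b:
        raise ValueError(f"require a <= b, got a={a}, b={b}")
    qa, qb = curve.q[a], curve.q[b]
    if qa >= 1.0:
        warnings.warn(f"Q({a}) = 1: everyone already affected; interval risk defined as 0")
        risk = 0.0
    else:
        risk = (qb - qa) / (1.0 - qa)
    return IntervalRisk(gene=curve.gene, endpoint=curve.endpoint, a=a, b=b, risk=risk)


def compose_interval_risks(p_ab: float, p_bc: float) -> float:
    """Combine consecutive conditional risks: 1 - (1-p_ab)(1-p_bc)."""
    for p in (p_ab, p_bc):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability out of range: {p}")
    return 1.0 - (1.0 - p_ab) * (1.0 - p_bc)
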