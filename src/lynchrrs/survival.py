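"""Crude Kaplan-Meier survival after cancer and combined-endpoint interpolation.

Crude survival treats death from any cause as the event, measured from age at
diagnosis to death or last observation. Survival is pooled across genes and
diagnosis ages (case numbers per gene are too small for stratified curves).

For the combined endometrial-and/or-ovarian endpoint the survival shown for an
age group is interpolated between the endpoint-specific values by the
endometrial share of risk:

    combined = OC_survival + (EC_survival - OC_survival) * EC_fraction,
    EC_fraction = EC_risk / (EC_risk + OC_risk).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .cohort_io import Cohort


@dataclass
class CancerCase:
    """One post-diagnosis follow-up interval."""

    gene: str
    endpoint: str  # EC or OC
    age_dx: float
    age_end: float
    died: bool
    died_of_followup_cancer: bool = False

    @property
    def followup(self) -> float:
        return self.age_end - self.age_dx


@dataclass
class SurvivalCurve:
    """Kaplan-Meier step function of crude survival since diagnosis."""

    endpoint: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_cases: int


@dataclass
class CombinedSurvivalParams:
    ec_survival: float
    oc_survival: float
    ec_fraction: float

    @property
    def surv_diff(self) -> float:
        """EC minus OC survival; always recomputed, never stored."""
        return self.ec_survival - self.oc_survival


def extract_cases(
    cohort: Cohort, endpoint: str, genes: tuple[str, ...] | None = None
) -> list[CancerCase]:
    """Post-diagnosis cases for one endpoint from a validated cohort.

    Previous cancers (diagnosed at or before inclusion) are not prospective
    cases and are skipped.
    """
    if endpoint not in ("EC", "OC"):
        raise ValueError(f"endpoint must be EC or OC, got {endpoint!r}")
    cases = []
    for rec in cohort.records:
        if genes is not None and rec.gene not in genes:
            continue
        dx = rec.age_ec_dx if endpoint == "EC" else rec.age_oc_dx
        previous = rec.previous_ec if endpoint == "EC" else rec.previous_oc
        if dx is None or previous:
            continue
        end = rec.age_death if rec.age_death is not None else rec.age_last_obs
        cases.append(CancerCase(
            gene=rec.gene,
            endpoint=endpoint,
            age_dx=dx,
            age_end=max(end, dx),
            died=rec.age_death is not None,
            died_of_followup_cancer=rec.died_of_followup_cancer,
        ))
    return cases


def kaplan_meier(cases: list[CancerCase], cancer_deaths_only: bool = False) -> SurvivalCurve:
    """Product-limit estimate of crude survival from diagnosis.

    All-cause death is the event by default (crude survival); with
    ``cancer_deaths_only`` deaths not attributed to the followed cancer are
    censored instead (sensitivity analysis). Deaths tied with censorings at
    the same time are processed first, the standard convention.
    """
    if not cases:
        raise ValueError("kaplan_meier requires at least one case")
    durations = np.array([c.followup for c in cases], dtype=float)
    if cancer_deaths_only:
        events = np.array([c.died and c.died_of_followup_cancer for c in cases], dtype=bool)
    else:
        events = np.array([c.died for c in cases], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    survival = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    endpoint = cases[0].endpoint if len({c.endpoint for c in cases}) == 1 else "pooled"
    return SurvivalCurve(endpoint=endpoint, times=times, survival=survival,
                         at_risk=at_risk, n_cases=len(cases))


def survival_at(curve: SurvivalCurve, t: float) -> float:
    """Right-continuous step-function value S(t).

    Beyond the last observed time the last value is carried forward with an
    extrapolation warning.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if t > curve.times[-1]:
        warnings.warn(
            f"survival_at({t}): beyond max follow-up {curve.times[-1]:.2f}; "
            "returning last value (extrapolation)"
        )
        return float(curve.survival[-1])
    idx = np.searchsorted(curve.times, t, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.survival[idx])


def ec_fraction(ec_risk: float, oc_risk: float) -> float:
    """Endometrial share of combined gynecological risk."""
    for p in (ec_risk, oc_risk):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"risk out of range: {p}")
    total = ec_risk + oc_risk
    if total == 0.0:
        raise ValueError("undefined fraction; no combined risk")
    return ec_risk / total


def combined_survival(params: CombinedSurvivalParams) -> float:
    """Interpolated survival after endometrial and/or ovarian cancer."""
    if not (0.0 <= params.ec_fraction <= 1.0):
        raise ValueError(f"ec_fraction out of range: {params.ec_fraction}")
    s = params.oc_survival + params.surv_diff * params.ec_fraction
    lo = min(params.oc_survival, params.ec_survival)
    hi = max(params.oc_survival, params.ec_survival)
    assert lo - 1e-12 <= s <= hi + 1e-12
    return s
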