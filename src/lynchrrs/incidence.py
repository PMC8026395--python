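"""Person-years at risk and annual incidence rates in 5-year age bins.

Observation time runs from inclusion (never before 25) to the earliest of
last observation, organ removal, diagnosis, or age 75. Bins are half-open
[s, s+5) for s in 25..70. A woman whose endpoint cancer predates inclusion
contributes no time; an event is counted once, in the bin containing the
diagnosis age, and her at-risk time stops there. An event at the same age as
surgery counts as an event and then censoring (prospective registries record
occult cancers found at risk-reducing surgery as cancers).

For the combined endpoint a woman stays at risk while at least one organ is
intact (``combined_censoring="both-organs"``, the default); the alternative
``"any-surgery"`` censors combined time at the first organ removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats

from .cohort_io import Cohort, FollowUpRecord, GENES

logger = logging.getLogger(__name__)

ENDPOINTS = ("EC", "OC", "EC_or_OC")
BIN_STARTS = tuple(range(25, 75, 5))
BIN_WIDTH = 5
MAX_AGE = 75.0
DEFAULT_MIN_PERSON_YEARS = 10.0


@dataclass
class AgeBinIncidence:
    """Events, person-years and annual incidence rate for one 5-year bin."""

    gene: str
    endpoint: str
    bin_start: int
    events: int = 0
    person_years: float = 0.0
    air: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    unreliable: bool = False


def _at_risk_interval(
    rec: FollowUpRecord, endpoint: str, combined_censoring: str
) -> tuple[float, float, float | None]:
    """(start, end, event_age) of the at-risk interval; event_age None if censored.

    Returns start >= end for records contributing no time.
    """
    start = max(rec.age_inclusion, 25.0)
    censors = [rec.age_last_obs, MAX_AGE]

    if endpoint == "EC":
        if rec.previous_ec:
            return start, start, None
        if rec.age_hysterectomy is not None:
            censors.append(rec.age_hysterectomy)
        event = rec.age_ec_dx if rec.age_ec_dx is not None and not rec.previous_ec else None
    elif endpoint == "OC":
        if rec.previous_oc:
            return start, start, None
        if rec.age_bso is not None:
            censors.append(rec.age_bso)
        event = rec.age_oc_dx if rec.age_oc_dx is not None and not rec.previous_oc else None
    elif endpoint == "EC_or_OC":
        if rec.previous_ec or rec.previous_oc:
            return start, start, None
        if combined_censoring == "any-surgery":
            surgeries = [a for a in (rec.age_hysterectomy, rec.age_bso) if a is not None]
            if surgeries:
                censors.append(min(surgeries))
        elif combined_censoring == "both-organs":
            if rec.age_hysterectomy is not None and rec.age_bso is not None:
                censors.append(max(rec.age_hysterectomy, rec.age_bso))
        else:
            raise ValueError(f"unknown combined_censoring mode: {combined_censoring!r}")
        dx = [a for a in (rec.age_ec_dx, rec.age_oc_dx) if a is not None]
        event = min(dx) if dx else None
    else:
        raise ValueError(f"unknown endpoint: {endpoint!r}")

    censor = min(censors)
    if event is not None and event <= censor and event < MAX_AGE:
        # tie with surgery counts as an event, then censoring
        return start, event, event
    return start, min(censor, MAX_AGE), None


def person_years(
    cohort: Cohort,
    endpoint: str,
    gene: str,
    combined_censoring: str = "both-organs",
) -> list[AgeBinIncidence]:
    """Per-bin events and person-years for one gene x endpoint.

    The exact fractional overlap of each woman's at-risk interval with each
    half-open bin [s, s+5) is accumulated; the event is counted once in the
    bin containing the diagnosis age.
    """
    if gene not in GENES:
        raise ValueError(f"unknown gene: {gene!r}")
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint: {endpoint!r}")
    bins = {s: AgeBinIncidence(gene=gene, endpoint=endpoint, bin_start=s) for s in BIN_STARTS}
    for rec in cohort.records:
        if rec.gene != gene:
            continue
        start, end, event = _at_risk_interval(rec, endpoint, combined_censoring)
        if end <= start:
            continue
        for s in BIN_STARTS:
            overlap = min(end, s + BIN_WIDTH) - max(start, float(s))
            if overlap > 0:
                bins[s].person_years += overlap
        if event is not None and start <= event < MAX_AGE:
            s = min(70, 25 + int((event - 25) // BIN_WIDTH) * BIN_WIDTH)
            bins[s].events += 1
    for b in bins.values():
        b.person_years = round(b.person_years, 6)
    return [bins[s] for s in BIN_STARTS]


def annual_incidence_rates(
    bins: list[AgeBinIncidence],
    min_py: float = DEFAULT_MIN_PERSON_YEARS,
    ci_level: float | None = None,
) -> list[AgeBinIncidence]:
    """Fill annual incidence rates (events / person-years) into the bins.

    Bins with fewer than ``min_py`` person-years are flagged unreliable; a bin
    with zero person-years has an undefined rate (``air=None``), is flagged,
    and is treated as zero downstream with a warning.
    """
    for b in bins:
        if b.person_years > 0:
            b.air = b.events / b.person_years
            if ci_level is not None:
                b.ci_low, b.ci_high = poisson_ci(b.events, b.person_years, ci_level)
        else:
            b.air = None
            logger.warning(
                "bin %d (%s %s): zero person-years, AIR undefined; treated as 0 downstream",
                b.bin_start, b.gene, b.endpoint,
            )
        b.unreliable = b.person_years < min_py
    return bins


def poisson_ci(events: int, person_years: float, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) Poisson confidence interval for an incidence rate."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    alpha = 1.0 - level
    low = 0.0 if events == 0 else stats.chi2.ppf(alpha / 2, 2 * events) / 2 / person_years
    high = stats.chi2.ppf(1 - alpha / 2, 2 * events + 2) / 2 / person_years
    return float(low), float(high)
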