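"""Data model, CSV reader/writer, and validation for prospective follow-up records.

A cohort is one row per female mismatch-repair-variant heterozygote under
prospective follow-up: her gene, observation window, optional risk-reducing
surgeries (hysterectomy, bilateral salpingo-oophorectomy), optional incident
endometrial (EC) and ovarian (OC) cancer diagnoses, and vital status.

Ages are fractional years at 0.01-year resolution so person-year arithmetic is
exact. A cancer diagnosed at or before the inclusion age is a *previous*
cancer: the record is kept but contributes nothing to incidence for that
endpoint. Missing optional ages are empty CSV cells, never sentinel numbers.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import pandas as pd

GENES = ("MLH1", "MSH2", "MSH6", "PMS2")

MIN_INCLUSION_AGE = 25.0
MAX_INCLUSION_AGE = 74.0
MIN_FOLLOWUP_YEARS = 1.0
AGE_RESOLUTION = 0.01

CSV_COLUMNS = [
    "id",
    "gene",
    "age_inclusion",
    "age_last_obs",
    "age_hysterectomy",
    "age_bso",
    "age_ec_dx",
    "age_oc_dx",
    "age_death",
    "died_of_followup_cancer",
]

_OPTIONAL_AGE_FIELDS = ("age_hysterectomy", "age_bso", "age_ec_dx", "age_oc_dx", "age_death")

# machine-readable rejection codes -> human-readable explanations
REASON_TEXT = {
    "unknown_gene": "gene symbol not one of MLH1/MSH2/MSH6/PMS2",
    "inclusion_age_out_of_range": "inclusion age out of range [25,74]",
    "followup_too_short": "follow-up shorter than one year",
    "surgery_outside_window": "surgery age outside [age_inclusion, age_last_obs]",
    "death_outside_window": "death age outside [age_inclusion, age_last_obs]",
    "cancer_after_last_obs": "cancer diagnosis age after age_last_obs",
    "ec_after_hysterectomy": "endometrial cancer diagnosed after hysterectomy",
    "oc_after_bso": "ovarian cancer diagnosed after bilateral salpingo-oophorectomy",
    "death_flag_without_events": "died_of_followup_cancer set without both a cancer and a death age",
    "duplicate_id": "record id duplicates an earlier row",
}


class CohortFormatError(ValueError):
    """The CSV cannot be parsed: missing columns, bad ages, unknown symbols."""


class CohortValidationError(ValueError):
    """A record violates cohort invariants (raised in strict mode)."""


def _round_age(x: float) -> float:
    return round(round(x / AGE_RESOLUTION) * AGE_RESOLUTION, 2)


@dataclass
class FollowUpRecord:
    """One woman's prospective observation window, surgeries, cancers, vital status."""

    id: str
    gene: str
    age_inclusion: float
    age_last_obs: float
    age_hysterectomy: float | None = None
    age_bso: float | None = None
    age_ec_dx: float | None = None
    age_oc_dx: float | None = None
    age_death: float | None = None
    died_of_followup_cancer: bool = False

    def __post_init__(self) -> None:
        self.age_inclusion = _round_age(self.age_inclusion)
        self.age_last_obs = _round_age(self.age_last_obs)
        for name in _OPTIONAL_AGE_FIELDS:
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, _round_age(v))

    @property
    def previous_ec(self) -> bool:
        """EC diagnosed at or before inclusion: excluded from EC incidence."""
        return self.age_ec_dx is not None and self.age_ec_dx <= self.age_inclusion

    @property
    def previous_oc(self) -> bool:
        """OC diagnosed at or before inclusion: excluded from OC incidence."""
        return self.age_oc_dx is not None and self.age_oc_dx <= self.age_inclusion

    def validation_errors(self) -> list[str]:
        """All invariant violations as machine-readable reason codes."""
        reasons: list[str] = []
        if self.gene not in GENES:
            reasons.append("unknown_gene")
        if not (MIN_INCLUSION_AGE <= self.age_inclusion <= MAX_INCLUSION_AGE):
            reasons.append("inclusion_age_out_of_range")
        # small slack so 0.01-resolution arithmetic cannot flip the comparison
        if self.age_last_obs - self.age_inclusion < MIN_FOLLOWUP_YEARS - 1e-9:
            reasons.append("followup_too_short")
        for name in ("age_hysterectomy", "age_bso"):
            v = getattr(self, name)
            if v is not None and not (self.age_inclusion <= v <= self.age_last_obs):
                reasons.append("surgery_outside_window")
                break
        if self.age_death is not None and not (
            self.age_inclusion <= self.age_death <= self.age_last_obs
        ):
            reasons.append("death_outside_window")
        # previous cancers (dx <= inclusion) are allowed; only a dx beyond the
        # observation window is inconsistent
        for name in ("age_ec_dx", "age_oc_dx"):
            v = getattr(self, name)
            if v is not None and v > self.age_last_obs:
                reasons.append("cancer_after_last_obs")
                break
        if (
            self.age_ec_dx is not None
            and self.age_hysterectomy is not None
            and self.age_ec_dx > self.age_hysterectomy
        ):
            reasons.append("ec_after_hysterectomy")
        if (
            self.age_oc_dx is not None
            and self.age_bso is not None
            and self.age_oc_dx > self.age_bso
        ):
            reasons.append("oc_after_bso")
        if self.died_of_followup_cancer and (
            self.age_death is None or (self.age_ec_dx is None and self.age_oc_dx is None)
        ):
            reasons.append("death_flag_without_events")
        return reasons


@dataclass
class Rejection:
    """Why a row was dropped during validation."""

    row: int  # 0-based data-row index in the source file
    id: str
    reasons: list[str]

    @property
    def messages(self) -> list[str]:
        return [REASON_TEXT.get(r, r) for r in self.reasons]


@dataclass
class Cohort:
    records: list[FollowUpRecord]
    provenance: dict = field(default_factory=dict)
    rejections: list[Rejection] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, gene: str) -> "Cohort":
        return Cohort(
            records=[r for r in self.records if r.gene == gene],
            provenance=dict(self.provenance, subset_gene=gene),
        )


def _parse_age(value, row: int, column: str) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s == "":
        return None
    try:
        return float(s)
    except ValueError:
        raise CohortFormatError(f"row {row}: unparseable age in column '{column}': {s!r}") from None


def _parse_bool(value, row: int) -> bool:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return False
    s = str(value).strip().lower()
    if s in ("", "false", "0"):
        return False
    if s in ("true", "1"):
        return True
    raise CohortFormatError(f"row {row}: unparseable boolean in column 'died_of_followup_cancer': {value!r}")


def read_cohort(path: str | os.PathLike | io.IOBase, strict: bool = False) -> Cohort:
    """Read and validate a follow-up cohort from CSV.

    In non-strict mode invalid rows are dropped and reported in
    ``Cohort.rejections`` with machine-readable reason codes; in strict mode
    the first invalid row raises :class:`CohortValidationError`. Structural
    problems (missing columns, unparseable cells) always raise
    :class:`CohortFormatError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing required columns: {', '.join(missing)}")

    records: list[FollowUpRecord] = []
    rejections: list[Rejection] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        rid = str(getattr(row, "id")).strip()
        gene = str(getattr(row, "gene")).strip()
        age_inclusion = _parse_age(getattr(row, "age_inclusion"), i, "age_inclusion")
        age_last_obs = _parse_age(getattr(row, "age_last_obs"), i, "age_last_obs")
        if age_inclusion is None or age_last_obs is None:
            raise CohortFormatError(f"row {i}: age_inclusion and age_last_obs are required")
        rec = FollowUpRecord(
            id=rid,
            gene=gene,
            age_inclusion=age_inclusion,
            age_last_obs=age_last_obs,
            age_hysterectomy=_parse_age(getattr(row, "age_hysterectomy"), i, "age_hysterectomy"),
            age_bso=_parse_age(getattr(row, "age_bso"), i, "age_bso"),
            age_ec_dx=_parse_age(getattr(row, "age_ec_dx"), i, "age_ec_dx"),
            age_oc_dx=_parse_age(getattr(row, "age_oc_dx"), i, "age_oc_dx"),
            age_death=_parse_age(getattr(row, "age_death"), i, "age_death"),
            died_of_followup_cancer=_parse_bool(getattr(row, "died_of_followup_cancer"), i),
        )
        reasons = rec.validation_errors()
        if rec.id in seen_ids:
            reasons.append("duplicate_id")
        if reasons:
            if strict:
                details = "; ".join(REASON_TEXT.get(r, r) for r in reasons)
                raise CohortValidationError(f"row {i} (id={rec.id}): {details}")
            rejections.append(Rejection(row=i, id=rec.id, reasons=reasons))
            continue
        seen_ids.add(rec.id)
        records.append(rec)

    source = getattr(path, "name", str(path))
    return Cohort(records=records, provenance={"source": source}, rejections=rejections)


def write_cohort(cohort: Cohort, path: str | os.PathLike | io.IOBase) -> None:
    """Write a cohort to CSV; read∘write is identity on all record fields."""

    def fmt(v: float | None) -> str:
        return "" if v is None else f"{v:.2f}"

    rows = [
        {
            "id": r.id,
            "gene": r.gene,
            "age_inclusion": fmt(r.age_inclusion),
            "age_last_obs": fmt(r.age_last_obs),
            "age_hysterectomy": fmt(r.age_hysterectomy),
            "age_bso": fmt(r.age_bso),
            "age_ec_dx": fmt(r.age_ec_dx),
            "age_oc_dx": fmt(r.age_oc_dx),
            "age_death": fmt(r.age_death),
            "died_of_followup_cancer": "true" if r.died_of_followup_cancer else "false",
        }
        for r in cohort.records
    ]
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


def copy_record(rec: FollowUpRecord, **changes) -> FollowUpRecord:
    """Functional update helper (used by tests and the simulator)."""
    return replace(rec, **changes)
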