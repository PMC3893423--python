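"""Record types shared across the phenotyping and validation pipeline.

The pipeline operates on five per-participant record kinds: the baseline
self-completed questionnaire, hospital admissions coded in ICD-10-AM,
medical-service claims (HbA1c pathology items), pharmacy dispensing claims,
and record-linkage status flags.  Linkage itself is out of scope and is
represented by boolean flags per participant.

All types are plain dataclasses; each carries a ``problems()`` method that
returns human-readable invariant violations (empty list when valid), which
the CSV readers use to produce row-addressed diagnostics.
"""

from __future__ import annotations

import datetime as dt
import math
import re
from dataclasses import dataclass

SEXES = ("female", "male")

#: Closed set of medication classes used by both the questionnaire lexicon
#: and the pharmacy dispensing records.
MEDICATION_CLASSES = (
    "insulin",
    "biguanide",
    "sulphonylurea",
    "thiazolidinedione",
    "alpha_glucosidase_inhibitor",
    "dpp4_inhibitor",
    "premixed_oha",
    "exenatide",
    "meglitinide",
    "non_diabetes",
)

#: Oral hypoglycaemic agent classes (everything diabetes-related that is
#: not insulin).
OHA_CLASSES = tuple(
    c for c in MEDICATION_CLASSES if c not in ("insulin", "non_diabetes")
)

STATUSES = ("diabetes", "non_diabetes", "uncertain")
EVIDENCE_SOURCES = ("tickbox", "free_text", "insulin_text", "oha_text", "none")
DIABETES_TYPES = ("type1", "type2", "gestational_other", "not_applicable")
APDC_TYPES = (
    "type1",
    "type2",
    "gestational_other",
    "unspecified",
    "no_diabetes_code",
    "not_applicable",
)
CRITERION_SOURCES = ("apdc", "mbs", "pbs")
EXCLUSION_REASONS = (
    "not_linked",
    "no_admission",
    "diagnosed_after_last_admission",
    "gestational_only",
    "diagnosis_after_window",
    "dva_card",
    "no_pbs_claims",
    "none",
)

# ICD-10-AM lexical shape: letter, two or three digits, optional dot suffix.
_ICD_PATTERN = re.compile(r"^[A-Z][0-9]{2,3}(\.[0-9A-Z]{1,4})?$")


@dataclass(slots=True)
class QuestionnaireRecord:
    """One participant's baseline self-report fields.

    ``diabetes_tickbox`` is the response to "Has a doctor EVER told you that
    you have diabetes?" (None = not answered).  ``other_illness_text`` is the
    free-text "any other important illness" box; ``medication_text`` the
    free-text medication box; ``metformin_tickbox`` the dedicated tick box
    for Diabex / Diaformin / Metformin.
    """

    participant_id: str
    recruitment_date: dt.date
    sex: str
    year_of_birth: int
    diabetes_tickbox: bool | None
    age_at_diagnosis: int | None
    other_illness_text: str
    metformin_tickbox: bool
    medication_text: str
    dva_card: bool
    age_at_last_delivery: int | None

    @property
    def recruitment_age(self) -> int:
        return self.recruitment_date.year - self.year_of_birth

    def problems(self) -> list[str]:
        issues: list[str] = []
        if not self.participant_id:
            issues.append("participant_id is empty")
        if self.sex not in SEXES:
            issues.append(f"sex {self.sex!r} not in {SEXES}")
        if self.age_at_diagnosis is not None and not (
            0 <= self.age_at_diagnosis <= self.recruitment_age
        ):
            issues.append(
                f"age_at_diagnosis {self.age_at_diagnosis} outside "
                f"[0, recruitment age {self.recruitment_age}]"
            )
        if self.age_at_last_delivery is not None and self.sex != "female":
            issues.append("age_at_last_delivery present for non-female participant")
        return issues


@dataclass(slots=True)
class AdmissionRecord:
    """A hospital admission with its ordered ICD-10-AM diagnosis codes.

    The first code is the principal diagnosis; the remainder are additional
    diagnoses.  Diabetes codes count in any position.
    """

    participant_id: str
    admission_date: dt.date
    diagnosis_codes: tuple[str, ...]

    def problems(self) -> list[str]:
        issues: list[str] = []
        if not self.diagnosis_codes:
            issues.append("diagnosis_codes is empty")
        for code in self.diagnosis_codes:
            if not _ICD_PATTERN.match(code):
                issues.append(f"code {code!r} is not a valid ICD-10-AM code")
        return issues


@dataclass(slots=True)
class MbsClaim:
    """A medical-service claim (item 66551 = HbA1c test)."""

    participant_id: str
    service_date: dt.date
    item_number: int

    def problems(self) -> list[str]:
        return [] if self.item_number > 0 else ["item_number must be positive"]


@dataclass(slots=True)
class PbsClaim:
    """A pharmacy dispensing claim labelled with its medication class."""

    participant_id: str
    supply_date: dt.date
    medication_class: str

    def problems(self) -> list[str]:
        if self.medication_class not in MEDICATION_CLASSES:
            return [
                f"medication_class {self.medication_class!r} not in closed set"
            ]
        return []


@dataclass(slots=True)
class LinkageStatus:
    """Outcome of person-level linkage to each administrative collection."""

    participant_id: str
    linked_apdc: bool
    linked_medicare: bool

    def problems(self) -> list[str]:
        return [] if self.participant_id else ["participant_id is empty"]


@dataclass(slots=True)
class PhenotypeAssignment:
    """Three-way diabetes status with its evidence path and diabetes type."""

    participant_id: str
    status: str
    evidence: str
    self_reported_insulin: bool
    self_reported_oha: bool
    diabetes_type: str = "not_applicable"

    def problems(self) -> list[str]:
        issues: list[str] = []
        if self.status not in STATUSES:
            issues.append(f"status {self.status!r} not in {STATUSES}")
        if self.evidence not in EVIDENCE_SOURCES:
            issues.append(f"evidence {self.evidence!r} unknown")
        if self.diabetes_type not in DIABETES_TYPES:
            issues.append(f"diabetes_type {self.diabetes_type!r} unknown")
        if self.status == "diabetes" and self.evidence not in (
            "tickbox",
            "free_text",
            "insulin_text",
        ):
            issues.append("diabetes status requires tickbox/free_text/insulin_text")
        if self.status != "diabetes" and self.diabetes_type != "not_applicable":
            issues.append("diabetes_type set for non-diabetes status")
        if (self.evidence == "none") != (self.status == "non_diabetes"):
            issues.append("evidence 'none' must coincide with non_diabetes status")
        return issues


@dataclass(slots=True)
class CriterionResult:
    """Inclusion decision and criterion-standard indicator for one source."""

    participant_id: str
    source: str
    included: bool
    exclusion_reason: str
    criterion_positive: bool | None = None
    apdc_type: str = "not_applicable"

    def problems(self) -> list[str]:
        issues: list[str] = []
        if self.source not in CRITERION_SOURCES:
            issues.append(f"source {self.source!r} unknown")
        if self.exclusion_reason not in EXCLUSION_REASONS:
            issues.append(f"exclusion_reason {self.exclusion_reason!r} unknown")
        if self.included != (self.exclusion_reason == "none"):
            issues.append("included must coincide with exclusion_reason == 'none'")
        if self.included and self.criterion_positive is None:
            issues.append("criterion_positive undefined for included participant")
        if not self.included and self.criterion_positive is not None:
            issues.append("criterion_positive defined for excluded participant")
        return issues


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 cross-tabulation: rows = self-report, columns = criterion standard.

    ``tp``  self-report diabetes  & criterion positive
    ``fp``  self-report diabetes  & criterion negative
    ``fn``  self-report non-diabetes & criterion positive
    ``tn``  self-report non-diabetes & criterion negative
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"ConfusionTable.{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def criterion_positive_total(self) -> int:
        return self.tp + self.fn

    @property
    def criterion_negative_total(self) -> int:
        return self.fp + self.tn

    @property
    def self_report_positive_total(self) -> int:
        return self.tp + self.fp

    @property
    def self_report_negative_total(self) -> int:
        return self.fn + self.tn

    def transpose(self) -> "ConfusionTable":
        """Swap the two raters (self-report <-> criterion standard)."""
        return ConfusionTable(tp=self.tp, fp=self.fn, fn=self.fp, tn=self.tn)


@dataclass(frozen=True)
class AgreementStats:
    """Agreement statistics derived from a :class:`ConfusionTable`.

    All fields are proportions in [0, 1] except ``kappa`` in [-1, 1].
    A statistic whose denominator is zero is reported as ``nan``
    (undefined), never as 0.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    observed_agreement: float
    expected_agreement: float
    kappa: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "observed_agreement": self.observed_agreement,
            "expected_agreement": self.expected_agreement,
            "kappa": self.kappa,
        }


@dataclass(frozen=True)
class WindowConfig:
    """Date windows, item numbers and thresholds for the criterion standards.

    Defaults reflect the study design: hospital data extracted for
    1 July 2000 - 31 December 2009 (closed interval), HbA1c claims counted
    over calendar years 2005-2009, pharmacy lookback of 365 days before
    recruitment (recruitment day excluded).
    """

    apdc_start: dt.date = dt.date(2000, 7, 1)
    apdc_end: dt.date = dt.date(2009, 12, 31)
    hba1c_year_start: int = 2005
    hba1c_year_end: int = 2009
    hba1c_item: int = 66551
    hba1c_min_claims: int = 1
    pbs_lookback_days: int = 365
    gestational_prefixes: tuple[str, ...] = ("O24",)

    def __post_init__(self) -> None:
        if self.apdc_start > self.apdc_end:
            raise ValueError("apdc window is empty")
        if self.hba1c_year_start > self.hba1c_year_end:
            raise ValueError("hba1c window is empty")
        if self.hba1c_min_claims < 1:
            raise ValueError("hba1c_min_claims must be >= 1")
        if self.pbs_lookback_days < 1:
            raise ValueError("pbs_lookback_days must be >= 1")


@dataclass(slots=True)
class CohortBundle:
    """All record collections for one cohort, keyed consistently by
    participant_id (unique within the questionnaire collection)."""

    questionnaires: list[QuestionnaireRecord]
    admissions: list[AdmissionRecord]
    mbs_claims: list[MbsClaim]
    pbs_claims: list[PbsClaim]
    linkage: list[LinkageStatus]

    @property
    def n(self) -> int:
        return len(self.questionnaires)

    def linkage_by_id(self) -> dict[str, LinkageStatus]:
        return {l.participant_id: l for l in self.linkage}


def nan_if_zero_denominator(num: float, den: float) -> float:
    """Proportion ``num/den``; undefined (nan) when the denominator is 0."""
    return num / den if den > 0 else math.nan


__all__ = [
    "QuestionnaireRecord",
    "AdmissionRecord",
    "MbsClaim",
    "PbsClaim",
    "LinkageStatus",
    "PhenotypeAssignment",
    "CriterionResult",
    "ConfusionTable",
    "AgreementStats",
    "WindowConfig",
    "CohortBundle",
    "MEDICATION_CLASSES",
    "OHA_CLASSES",
    "STATUSES",
    "EVIDENCE_SOURCES",
    "DIABETES_TYPES",
    "APDC_TYPES",
    "CRITERION_SOURCES",
    "EXCLUSION_REASONS",
    "nan_if_zero_denominator",
]
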