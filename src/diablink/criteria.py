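"""Criterion standards built from the linked administrative collections.

Three imperfect reference indicators of prevalent diabetes are constructed,
one per source, each over its own analysis subset:

* **APDC** (hospital admissions): any ICD-10-AM diabetes code (E10, E11,
  E13, E14, O24.0-O24.3) in any diagnostic position of any admission in
  the extraction window.  Participants are excluded if unlinked, never
  admitted in the window, self-reported a diagnosis year after their last
  admission year, or carry only gestational (O24) diabetes codes.
* **MBS** (medical-service claims): at least ``hba1c_min_claims`` claims
  for the HbA1c pathology item (66551) in the counting calendar years.
  Excluded if unlinked to Medicare or diagnosed after the window's end.
* **PBS** (pharmacy dispensing): at least one insulin or OHA dispensing in
  the 365 days before recruitment.  Excluded if unlinked, if no dispensing
  of any kind occurred in the lookback (no exposure to capture), or if the
  participant holds a DVA card (their dispensings bypass this collection).

ICD code matching is by prefix on the dot-retaining normalised code, so
"E11" covers "E11", "E11.9", "E11.64".  The self-reported diagnosis year is
``year_of_birth + age_at_diagnosis`` (the questionnaire records age, not
date, of diagnosis; comparisons are at year resolution).
"""

from __future__ import annotations

import datetime as dt
import logging
from collections import Counter, defaultdict

from .io import log_stage
from .records import (
    AdmissionRecord,
    CohortBundle,
    CriterionResult,
    LinkageStatus,
    MbsClaim,
    OHA_CLASSES,
    PbsClaim,
    QuestionnaireRecord,
    WindowConfig,
)

logger = logging.getLogger("diablink")

#: Non-gestational diabetes code prefixes.
E_CODE_PREFIXES = ("E10", "E11", "E13", "E14")
#: Pre-existing diabetes in pregnancy (counted as diabetes codes).
O24_DIABETES_PREFIXES = ("O24.0", "O24.1", "O24.2", "O24.3")


def normalise_code(code: str) -> str:
    return code.strip().upper()


def is_diabetes_code(code: str) -> bool:
    code = normalise_code(code)
    return code.startswith(E_CODE_PREFIXES) or code.startswith(O24_DIABETES_PREFIXES)


def diagnosis_year(record: QuestionnaireRecord) -> int | None:
    """Self-reported diagnosis year, or None when no age was given."""
    if record.age_at_diagnosis is None:
        return None
    return record.year_of_birth + record.age_at_diagnosis


def _admissions_in_window(
    admissions: list[AdmissionRecord], config: WindowConfig
) -> list[AdmissionRecord]:
    kept = []
    for adm in admissions:
        if config.apdc_start <= adm.admission_date <= config.apdc_end:
            kept.append(adm)
        else:
            logger.warning(
                "admission for %s on %s outside APDC window, ignored",
                adm.participant_id,
                adm.admission_date,
            )
    return kept


def apdc_type(admissions: list[AdmissionRecord]) -> str:
    """Hospital-coded diabetes type across all admissions.

    Precedence when multiple code families occur: E10 (type 1) > E11
    (type 2) > E13 / O24.0-O24.3 (gestational/other) > E14 (unspecified);
    no diabetes code at all -> 'no_diabetes_code'.  Multi-family conflicts
    are resolved by this order and logged by the cohort driver.
    """
    codes = {normalise_code(c) for adm in admissions for c in adm.diagnosis_codes}
    if any(c.startswith("E10") for c in codes):
        return "type1"
    if any(c.startswith("E11") for c in codes):
        return "type2"
    if any(c.startswith("E13") or c.startswith(O24_DIABETES_PREFIXES) for c in codes):
        return "gestational_other"
    if any(c.startswith("E14") for c in codes):
        return "unspecified"
    return "no_diabetes_code"


def apdc_criterion(
    record: QuestionnaireRecord,
    admissions: list[AdmissionRecord],
    linkage: LinkageStatus,
    config: WindowConfig,
) -> CriterionResult:
    """Hospital-data criterion standard for one participant."""
    pid = record.participant_id
    if not linkage.linked_apdc:
        return CriterionResult(pid, "apdc", False, "not_linked")
    in_window = _admissions_in_window(admissions, config)
    if not in_window:
        return CriterionResult(pid, "apdc", False, "no_admission")
    dx_year = diagnosis_year(record)
    last_admission_year = max(a.admission_date.year for a in in_window)
    if dx_year is not None and dx_year > last_admission_year:
        return CriterionResult(pid, "apdc", False, "diagnosed_after_last_admission")
    codes = {normalise_code(c) for adm in in_window for c in adm.diagnosis_codes}
    has_e_code = any(c.startswith(E_CODE_PREFIXES) for c in codes)
    has_gestational = any(c.startswith(config.gestational_prefixes) for c in codes)
    if has_gestational and not has_e_code:
        return CriterionResult(pid, "apdc", False, "gestational_only")
    positive = has_e_code or any(c.startswith(O24_DIABETES_PREFIXES) for c in codes)
    return CriterionResult(
        pid, "apdc", True, "none", criterion_positive=positive,
        apdc_type=apdc_type(in_window),
    )


def mbs_criterion(
    record: QuestionnaireRecord,
    claims: list[MbsClaim],
    linkage: LinkageStatus,
    config: WindowConfig,
) -> CriterionResult:
    """HbA1c-claim criterion standard for one participant."""
    pid = record.participant_id
    if not linkage.linked_medicare:
        return CriterionResult(pid, "mbs", False, "not_linked")
    dx_year = diagnosis_year(record)
    if dx_year is not None and dx_year > config.hba1c_year_end:
        return CriterionResult(pid, "mbs", False, "diagnosis_after_window")
    n_claims = sum(
        1
        for c in claims
        if c.item_number == config.hba1c_item
        and config.hba1c_year_start <= c.service_date.year <= config.hba1c_year_end
    )
    return CriterionResult(
        pid, "mbs", True, "none",
        criterion_positive=n_claims >= config.hba1c_min_claims,
    )


def pbs_criterion(
    record: QuestionnaireRecord,
    claims: list[PbsClaim],
    linkage: LinkageStatus,
    config: WindowConfig,
) -> CriterionResult:
    """Dispensing-claim criterion standard for one participant.

    The lookback window is [recruitment - lookback, recruitment): a claim on
    the recruitment day itself is not "prior to recruitment".
    """
    pid = record.participant_id
    if not linkage.linked_medicare:
        return CriterionResult(pid, "pbs", False, "not_linked")
    start = record.recruitment_date - dt.timedelta(days=config.pbs_lookback_days)
    in_window = [c for c in claims if start <= c.supply_date < record.recruitment_date]
    if not in_window:
        return CriterionResult(pid, "pbs", False, "no_pbs_claims")
    if record.dva_card:
        return CriterionResult(pid, "pbs", False, "dva_card")
    diabetes_classes = ("insulin",) + OHA_CLASSES
    positive = any(c.medication_class in diabetes_classes for c in in_window)
    return CriterionResult(pid, "pbs", True, "none", criterion_positive=positive)


# ---------------------------------------------------------------------------
# cohort drivers
# ---------------------------------------------------------------------------


def _group_by_id(events) -> dict[str, list]:
    grouped: dict[str, list] = defaultdict(list)
    for e in events:
        grouped[e.participant_id].append(e)
    return grouped


def _require_linkage(bundle: CohortBundle) -> dict[str, LinkageStatus]:
    linkage = bundle.linkage_by_id()
    missing = [q.participant_id for q in bundle.questionnaires if q.participant_id not in linkage]
    if missing:
        raise ValueError(
            f"{len(missing)} participants lack a linkage record (first: {missing[0]!r})"
        )
    return linkage


def apdc_criteria(
    bundle: CohortBundle, config: WindowConfig | None = None
) -> dict[str, CriterionResult]:
    config = config or WindowConfig()
    linkage = _require_linkage(bundle)
    admissions = _group_by_id(bundle.admissions)
    results = {
        q.participant_id: apdc_criterion(
            q, admissions.get(q.participant_id, []), linkage[q.participant_id], config
        )
        for q in bundle.questionnaires
    }
    _log_source("apdc", bundle.n, results)
    return results


def mbs_criteria(
    bundle: CohortBundle, config: WindowConfig | None = None
) -> dict[str, CriterionResult]:
    config = config or WindowConfig()
    linkage = _require_linkage(bundle)
    claims = _group_by_id(bundle.mbs_claims)
    results = {
        q.participant_id: mbs_criterion(
            q, claims.get(q.participant_id, []), linkage[q.participant_id], config
        )
        for q in bundle.questionnaires
    }
    _log_source("mbs", bundle.n, results)
    return results


def pbs_criteria(
    bundle: CohortBundle, config: WindowConfig | None = None
) -> dict[str, CriterionResult]:
    config = config or WindowConfig()
    linkage = _require_linkage(bundle)
    claims = _group_by_id(bundle.pbs_claims)
    results = {
        q.participant_id: pbs_criterion(
            q, claims.get(q.participant_id, []), linkage[q.participant_id], config
        )
        for q in bundle.questionnaires
    }
    _log_source("pbs", bundle.n, results)
    return results


def all_criteria(
    bundle: CohortBundle, config: WindowConfig | None = None
) -> dict[str, dict[str, CriterionResult]]:
    """Criterion results for all three sources, keyed by source name."""
    return {
        "apdc": apdc_criteria(bundle, config),
        "mbs": mbs_criteria(bundle, config),
        "pbs": pbs_criteria(bundle, config),
    }


def _log_source(source: str, n: int, results: dict[str, CriterionResult]) -> None:
    reasons = Counter(r.exclusion_reason for r in results.values() if not r.included)
    n_included = sum(1 for r in results.values() if r.included)
    log_stage(f"criterion[{source}]", n, dict(reasons), n_included)
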