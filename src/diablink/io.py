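"""Delimited-text readers and writers for the cohort record collections.

CSV dialect: comma-separated, UTF-8, mandatory header row, ISO-8601 dates,
missing values encoded as the empty string.  Admission diagnosis-code lists
are serialised as a single semicolon-delimited field so each admission is
one row.

Readers validate every row against the record-type invariants and raise
:class:`SchemaError` with 1-based file line numbers on the first batch of
violations (fatal, per the pipeline contract).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .records import (
    AdmissionRecord,
    CohortBundle,
    CriterionResult,
    LinkageStatus,
    MbsClaim,
    PbsClaim,
    PhenotypeAssignment,
    QuestionnaireRecord,
    WindowConfig,
)

logger = logging.getLogger("diablink")

#: Standard file names inside a cohort directory.
COHORT_FILES = {
    "questionnaires": "questionnaire.csv",
    "admissions": "admissions.csv",
    "mbs_claims": "mbs_claims.csv",
    "pbs_claims": "pbs_claims.csv",
    "linkage": "linkage.csv",
}

_MAX_REPORTED_ERRORS = 20


class SchemaError(ValueError):
    """A cohort file violates its documented schema; message carries
    row-addressed diagnostics."""


def _read_raw(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    if path.stat().st_size == 0:
        return pd.DataFrame(columns=columns)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def _fail(path: str | Path, errors: list[str]) -> None:
    if errors:
        shown = errors[:_MAX_REPORTED_ERRORS]
        more = len(errors) - len(shown)
        suffix = f" (+{more} more)" if more > 0 else ""
        raise SchemaError(f"{path}: " + "; ".join(shown) + suffix)


def _parse_bool(value: str, *, allow_missing: bool = False) -> bool | None:
    v = value.strip().lower()
    if v in ("true", "1", "yes", "y"):
        return True
    if v in ("false", "0", "no", "n"):
        return False
    if v == "" and allow_missing:
        return None
    raise ValueError(f"cannot parse boolean from {value!r}")


def _parse_opt_int(value: str) -> int | None:
    v = value.strip()
    return int(v) if v else None


def _parse_date(value: str) -> dt.date:
    return dt.date.fromisoformat(value.strip())


def _bool_str(value: bool | None) -> str:
    return "" if value is None else ("true" if value else "false")


def _opt_str(value) -> str:
    return "" if value is None else str(value)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

QUESTIONNAIRE_COLUMNS = [
    "participant_id",
    "recruitment_date",
    "sex",
    "year_of_birth",
    "diabetes_tickbox",
    "age_at_diagnosis",
    "other_illness_text",
    "metformin_tickbox",
    "medication_text",
    "dva_card",
    "age_at_last_delivery",
]


def read_questionnaires(path: str | Path) -> list[QuestionnaireRecord]:
    df = _read_raw(path, QUESTIONNAIRE_COLUMNS)
    records: list[QuestionnaireRecord] = []
    errors: list[str] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header line
        try:
            rec = QuestionnaireRecord(
                participant_id=row.participant_id.strip(),
                recruitment_date=_parse_date(row.recruitment_date),
                sex=row.sex.strip(),
                year_of_birth=int(row.year_of_birth),
                diabetes_tickbox=_parse_bool(row.diabetes_tickbox, allow_missing=True),
                age_at_diagnosis=_parse_opt_int(row.age_at_diagnosis),
                other_illness_text=row.other_illness_text,
                metformin_tickbox=_parse_bool(row.metformin_tickbox),
                medication_text=row.medication_text,
                dva_card=_parse_bool(row.dva_card),
                age_at_last_delivery=_parse_opt_int(row.age_at_last_delivery),
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {line}: {exc}")
            continue
        for issue in rec.problems():
            errors.append(f"row {line}: {issue}")
        if rec.participant_id in seen:
            errors.append(f"row {line}: duplicate participant_id {rec.participant_id!r}")
        seen.add(rec.participant_id)
        records.append(rec)
    _fail(path, errors)
    return records


def read_admissions(path: str | Path) -> list[AdmissionRecord]:
    df = _read_raw(path, ["participant_id", "admission_date", "diagnosis_codes"])
    records: list[AdmissionRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            codes = tuple(
                c.strip().upper() for c in row.diagnosis_codes.split(";") if c.strip()
            )
            rec = AdmissionRecord(
                participant_id=row.participant_id.strip(),
                admission_date=_parse_date(row.admission_date),
                diagnosis_codes=codes,
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {line}: {exc}")
            continue
        for issue in rec.problems():
            errors.append(f"row {line}: {issue}")
        records.append(rec)
    _fail(path, errors)
    return records


def read_mbs_claims(path: str | Path) -> list[MbsClaim]:
    df = _read_raw(path, ["participant_id", "service_date", "item_number"])
    records: list[MbsClaim] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            rec = MbsClaim(
                participant_id=row.participant_id.strip(),
                service_date=_parse_date(row.service_date),
                item_number=int(row.item_number),
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {line}: {exc}")
            continue
        for issue in rec.problems():
            errors.append(f"row {line}: {issue}")
        records.append(rec)
    _fail(path, errors)
    return records


def read_pbs_claims(path: str | Path) -> list[PbsClaim]:
    df = _read_raw(path, ["participant_id", "supply_date", "medication_class"])
    records: list[PbsClaim] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            rec = PbsClaim(
                participant_id=row.participant_id.strip(),
                supply_date=_parse_date(row.supply_date),
                medication_class=row.medication_class.strip(),
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {line}: {exc}")
            continue
        for issue in rec.problems():
            errors.append(f"row {line}: {issue}")
        records.append(rec)
    _fail(path, errors)
    return records


def read_linkage(path: str | Path) -> list[LinkageStatus]:
    df = _read_raw(path, ["participant_id", "linked_apdc", "linked_medicare"])
    records: list[LinkageStatus] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            rec = LinkageStatus(
                participant_id=row.participant_id.strip(),
                linked_apdc=_parse_bool(row.linked_apdc),
                linked_medicare=_parse_bool(row.linked_medicare),
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {line}: {exc}")
            continue
        records.append(rec)
    _fail(path, errors)
    return records


def read_cohort(directory: str | Path) -> CohortBundle:
    """Read a full cohort from ``directory`` using the standard file names.

    Enforces the cross-file invariant that every questionnaire participant
    has exactly one linkage record.
    """
    directory = Path(directory)
    bundle = CohortBundle(
        questionnaires=read_questionnaires(directory / COHORT_FILES["questionnaires"]),
        admissions=read_admissions(directory / COHORT_FILES["admissions"]),
        mbs_claims=read_mbs_claims(directory / COHORT_FILES["mbs_claims"]),
        pbs_claims=read_pbs_claims(directory / COHORT_FILES["pbs_claims"]),
        linkage=read_linkage(directory / COHORT_FILES["linkage"]),
    )
    link_ids = {l.participant_id for l in bundle.linkage}
    if len(link_ids) != len(bundle.linkage):
        raise SchemaError(f"{directory}: duplicate participant_id in linkage file")
    missing = [q.participant_id for q in bundle.questionnaires if q.participant_id not in link_ids]
    if missing:
        raise SchemaError(
            f"{directory}: {len(missing)} participants lack a linkage record "
            f"(first: {missing[0]!r})"
        )
    logger.info(
        "read cohort: %d participants, %d admissions, %d MBS claims, %d PBS claims",
        bundle.n, len(bundle.admissions), len(bundle.mbs_claims), len(bundle.pbs_claims),
    )
    return bundle


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_questionnaires(records: list[QuestionnaireRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "recruitment_date": [r.recruitment_date.isoformat() for r in records],
            "sex": [r.sex for r in records],
            "year_of_birth": [r.year_of_birth for r in records],
            "diabetes_tickbox": [_bool_str(r.diabetes_tickbox) for r in records],
            "age_at_diagnosis": [_opt_str(r.age_at_diagnosis) for r in records],
            "other_illness_text": [r.other_illness_text for r in records],
            "metformin_tickbox": [_bool_str(r.metformin_tickbox) for r in records],
            "medication_text": [r.medication_text for r in records],
            "dva_card": [_bool_str(r.dva_card) for r in records],
            "age_at_last_delivery": [_opt_str(r.age_at_last_delivery) for r in records],
        },
        columns=QUESTIONNAIRE_COLUMNS,
    )
    df.to_csv(path, index=False)


def write_admissions(records: list[AdmissionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "admission_date": [r.admission_date.isoformat() for r in records],
            "diagnosis_codes": [";".join(r.diagnosis_codes) for r in records],
        }
    )
    df.to_csv(path, index=False)


def write_mbs_claims(records: list[MbsClaim], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "service_date": [r.service_date.isoformat() for r in records],
            "item_number": [r.item_number for r in records],
        }
    )
    df.to_csv(path, index=False)


def write_pbs_claims(records: list[PbsClaim], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "supply_date": [r.supply_date.isoformat() for r in records],
            "medication_class": [r.medication_class for r in records],
        }
    )
    df.to_csv(path, index=False)


def write_linkage(records: list[LinkageStatus], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "linked_apdc": [_bool_str(r.linked_apdc) for r in records],
            "linked_medicare": [_bool_str(r.linked_medicare) for r in records],
        }
    )
    df.to_csv(path, index=False)


def write_cohort(bundle: CohortBundle, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_questionnaires(bundle.questionnaires, directory / COHORT_FILES["questionnaires"])
    write_admissions(bundle.admissions, directory / COHORT_FILES["admissions"])
    write_mbs_claims(bundle.mbs_claims, directory / COHORT_FILES["mbs_claims"])
    write_pbs_claims(bundle.pbs_claims, directory / COHORT_FILES["pbs_claims"])
    write_linkage(bundle.linkage, directory / COHORT_FILES["linkage"])


# ---------------------------------------------------------------------------
# phenotype assignments and criterion results
# ---------------------------------------------------------------------------

ASSIGNMENT_COLUMNS = [
    "participant_id",
    "status",
    "evidence",
    "self_reported_insulin",
    "self_reported_oha",
    "diabetes_type",
]


def write_assignments(assignments: list[PhenotypeAssignment], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "participant_id": [a.participant_id for a in assignments],
            "status": [a.status for a in assignments],
            "evidence": [a.evidence for a in assignments],
            "self_reported_insulin": [_bool_str(a.self_reported_insulin) for a in assignments],
            "self_reported_oha": [_bool_str(a.self_reported_oha) for a in assignments],
            "diabetes_type": [a.diabetes_type for a in assignments],
        },
        columns=ASSIGNMENT_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_assignments(path: str | Path) -> list[PhenotypeAssignment]:
    df = _read_raw(path, ASSIGNMENT_COLUMNS)
    records: list[PhenotypeAssignment] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            rec = PhenotypeAssignment(
                participant_id=row.participant_id.strip(),
                status=row.status.strip(),
                evidence=row.evidence.strip(),
                self_reported_insulin=_parse_bool(row.self_reported_insulin),
                self_reported_oha=_parse_bool(row.self_reported_oha),
                diabetes_type=row.diabetes_type.strip(),
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {line}: {exc}")
            continue
        for issue in rec.problems():
            errors.append(f"row {line}: {issue}")
        records.append(rec)
    _fail(path, errors)
    return records


CRITERION_COLUMNS = [
    "participant_id",
    "source",
    "included",
    "exclusion_reason",
    "criterion_positive",
    "apdc_type",
]


def write_criteria(results: list[CriterionResult], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in results],
            "source": [r.source for r in results],
            "included": [_bool_str(r.included) for r in results],
            "exclusion_reason": [r.exclusion_reason for r in results],
            "criterion_positive": [_bool_str(r.criterion_positive) for r in results],
            "apdc_type": [r.apdc_type for r in results],
        },
        columns=CRITERION_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_criteria(path: str | Path) -> list[CriterionResult]:
    df = _read_raw(path, CRITERION_COLUMNS)
    results: list[CriterionResult] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            rec = CriterionResult(
                participant_id=row.participant_id.strip(),
                source=row.source.strip(),
                included=_parse_bool(row.included),
                exclusion_reason=row.exclusion_reason.strip(),
                criterion_positive=_parse_bool(row.criterion_positive, allow_missing=True),
                apdc_type=row.apdc_type.strip(),
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {line}: {exc}")
            continue
        for issue in rec.problems():
            errors.append(f"row {line}: {issue}")
        results.append(rec)
    _fail(path, errors)
    return results


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration: criterion windows, lexicon location, seed."""

    windows: WindowConfig
    seed: int = 0
    lexicon_dir: Path | None = None


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML/JSON configuration file.

    Recognised keys (all optional): ``seed``, ``lexicon_dir`` and the
    :class:`WindowConfig` fields (``apdc_start``, ``apdc_end``,
    ``hba1c_year_start``, ``hba1c_year_end``, ``hba1c_item``,
    ``hba1c_min_claims``, ``pbs_lookback_days``, ``gestational_prefixes``).
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: configuration must be a mapping")
    window_kwargs = {}
    for key in (
        "apdc_start",
        "apdc_end",
        "hba1c_year_start",
        "hba1c_year_end",
        "hba1c_item",
        "hba1c_min_claims",
        "pbs_lookback_days",
        "gestational_prefixes",
    ):
        if key in raw:
            value = raw[key]
            if key in ("apdc_start", "apdc_end") and isinstance(value, str):
                value = dt.date.fromisoformat(value)
            if key == "gestational_prefixes":
                value = tuple(value)
            window_kwargs[key] = value
    return PipelineConfig(
        windows=WindowConfig(**window_kwargs),
        seed=int(raw.get("seed", 0)),
        lexicon_dir=Path(raw["lexicon_dir"]) if raw.get("lexicon_dir") else None,
    )


def log_stage(stage: str, n_in: int, excluded: dict[str, int], n_out: int) -> None:
    """One line per pipeline stage: input, exclusions by reason, output."""
    excl = ", ".join(f"{k}={v}" for k, v in excluded.items() if v) or "none"
    logger.info("%s: in=%d excluded[%s] out=%d", stage, n_in, excl, n_out)
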