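"""Classification of self-reported diabetes into type 1 / type 2 / other.

The baseline questionnaire never asks for diabetes type, so type is inferred
for the diabetes group from indirect evidence, in a fixed rule order:

1. free text declares type 1            -> type1
2. free text declares type 2            -> type2
3. insulin use and (diagnosed before age 31, i.e. age <= 30, or no age
   of diagnosis given)                  -> type1
4. female, diagnosed before the birth of her last child (strictly younger
   age; ties are not gestational) and no current diabetes medication
                                        -> gestational_other
5. otherwise                            -> type2

A declared type outranks the insulin/age rule when they conflict (e.g.
declared type 2 but on insulin since age 20); such conflicts are counted
and logged rather than silently resolved.  Gestational and "other" are
merged into a single output label.  Administrative data play no role here;
hospital-coded type is used only as a comparison standard downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace

from .records import PhenotypeAssignment, QuestionnaireRecord

logger = logging.getLogger("diablink")

_TYPE1_PATTERN = re.compile(r"(?<!\w)type\s*(?:1|i|one)(?!\w)")
_TYPE2_PATTERN = re.compile(r"(?<!\w)(?:type\s*(?:2|ii|two)|grade\s*2)(?!\w)")


def declared_type_from_text(text: str) -> str:
    """Extract a self-declared diabetes type from free text.

    Returns 'type1', 'type2' or 'none'.  Type 1 wins if both are written.
    """
    norm = " ".join(text.lower().split())
    if not norm:
        return "none"
    if _TYPE1_PATTERN.search(norm):
        return "type1"
    if _TYPE2_PATTERN.search(norm):
        return "type2"
    return "none"


@dataclass(frozen=True)
class TypeEvidence:
    """Inputs to the type classification, all taken from the participant's
    questionnaire record and phenotype assignment."""

    free_text_declared_type: str  # type1 | type2 | none
    uses_insulin: bool
    uses_oha: bool
    age_at_diagnosis: int | None
    sex: str
    age_at_last_delivery: int | None


def build_evidence(
    record: QuestionnaireRecord, assignment: PhenotypeAssignment
) -> TypeEvidence:
    return TypeEvidence(
        free_text_declared_type=declared_type_from_text(record.other_illness_text),
        uses_insulin=assignment.self_reported_insulin,
        uses_oha=assignment.self_reported_oha,
        age_at_diagnosis=record.age_at_diagnosis,
        sex=record.sex,
        age_at_last_delivery=record.age_at_last_delivery,
    )


def classify_type(evidence: TypeEvidence) -> str:
    """Apply the rule order in the module docstring; always returns one of
    'type1', 'type2', 'gestational_other'."""
    if evidence.free_text_declared_type == "type1":
        return "type1"
    if evidence.free_text_declared_type == "type2":
        return "type2"
    if evidence.uses_insulin and (
        evidence.age_at_diagnosis is None or evidence.age_at_diagnosis <= 30
    ):
        return "type1"
    if (
        evidence.sex == "female"
        and evidence.age_at_diagnosis is not None
        and evidence.age_at_last_delivery is not None
        and evidence.age_at_diagnosis < evidence.age_at_last_delivery
        and not (evidence.uses_insulin or evidence.uses_oha)
    ):
        return "gestational_other"
    return "type2"


def _insulin_age_rule_fires(evidence: TypeEvidence) -> bool:
    return evidence.uses_insulin and (
        evidence.age_at_diagnosis is None or evidence.age_at_diagnosis <= 30
    )


def type_cohort(
    assignments: list[PhenotypeAssignment],
    records: list[QuestionnaireRecord],
) -> tuple[list[PhenotypeAssignment], dict[str, int]]:
    """Assign a diabetes type to every diabetes-group participant.

    Non-diabetes and uncertain participants keep type 'not_applicable'.
    Returns the typed assignments and per-rule-path counts, including the
    number of declared-type vs insulin/age conflicts encountered.
    """
    by_id = {r.participant_id: r for r in records}
    missing = [a.participant_id for a in assignments if a.participant_id not in by_id]
    if missing:
        raise ValueError(
            f"{len(missing)} assignments lack a questionnaire record "
            f"(first: {missing[0]!r})"
        )
    typed: list[PhenotypeAssignment] = []
    counts = {
        "declared_type1": 0,
        "declared_type2": 0,
        "insulin_young_or_no_age": 0,
        "gestational_other": 0,
        "residual_type2": 0,
        "declared_vs_insulin_conflicts": 0,
    }
    per_type = {"type1": 0, "type2": 0, "gestational_other": 0}
    for a in assignments:
        if a.status != "diabetes":
            typed.append(a)
            continue
        ev = build_evidence(by_id[a.participant_id], a)
        label = classify_type(ev)
        if ev.free_text_declared_type == "type1":
            counts["declared_type1"] += 1
        elif ev.free_text_declared_type == "type2":
            counts["declared_type2"] += 1
            if _insulin_age_rule_fires(ev):
                counts["declared_vs_insulin_conflicts"] += 1
        elif _insulin_age_rule_fires(ev):
            counts["insulin_young_or_no_age"] += 1
        elif label == "gestational_other":
            counts["gestational_other"] += 1
        else:
            counts["residual_type2"] += 1
        per_type[label] += 1
        typed.append(replace_type(a, label))
    if counts["declared_vs_insulin_conflicts"]:
        logger.info(
            "diabetes typing: %d declared-type-2 participants also met the "
            "insulin/age type-1 rule (declared type kept)",
            counts["declared_vs_insulin_conflicts"],
        )
    counts.update({f"n_{k}": v for k, v in per_type.items()})
    return typed, counts


def replace_type(assignment: PhenotypeAssignment, label: str) -> PhenotypeAssignment:
    if assignment.status != "diabetes":
        raise ValueError(
            f"cannot assign a diabetes type to participant "
            f"{assignment.participant_id!r} with status {assignment.status!r}"
        )
    return replace(assignment, diabetes_type=label)
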