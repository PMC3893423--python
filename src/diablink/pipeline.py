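"""End-to-end driver: phenotype, type, build criteria, compute agreement."""

from __future__ import annotations

from dataclasses import dataclass

from .agreement import TypeCrosstab, ValidationResult, type_crosstab, validate_source
from .criteria import all_criteria
from .io import log_stage
from .phenotyping import Lexicons, PhenotypeCounts, phenotype_cohort
from .records import CohortBundle, CriterionResult, PhenotypeAssignment, WindowConfig
from .typing_rules import type_cohort

_SOURCE_LABELS = {
    "apdc": "self-report vs hospital diabetes diagnosis codes",
    "mbs": "self-report vs HbA1c test claims",
    "pbs": "self-report vs diabetes medication dispensings",
}


@dataclass(frozen=True)
class PipelineResult:
    assignments: list[PhenotypeAssignment]
    phenotype_counts: PhenotypeCounts
    typing_counts: dict[str, int]
    criteria: dict[str, dict[str, CriterionResult]]
    validations: list[ValidationResult]
    crosstab: TypeCrosstab

    def validation(self, source: str) -> ValidationResult:
        for v in self.validations:
            if v.source == source:
                return v
        raise KeyError(source)


def run_pipeline(
    bundle: CohortBundle,
    config: WindowConfig | None = None,
    lexicons: Lexicons | None = None,
) -> PipelineResult:
    """Run every stage on a cohort bundle and collect all outputs."""
    assignments, counts = phenotype_cohort(bundle.questionnaires, lexicons)
    log_stage(
        "phenotype",
        counts.cohort_size,
        {"uncertain": counts.uncertain_total},
        counts.diabetes_total + counts.non_diabetes,
    )
    typed, typing_counts = type_cohort(assignments, bundle.questionnaires)
    criteria = all_criteria(bundle, config)
    validations = [
        validate_source(source, _SOURCE_LABELS[source], typed, criteria[source])
        for source in ("apdc", "mbs", "pbs")
    ]
    crosstab = type_crosstab(typed, criteria["apdc"])
    return PipelineResult(
        assignments=typed,
        phenotype_counts=counts,
        typing_counts=typing_counts,
        criteria=criteria,
        validations=validations,
        crosstab=crosstab,
    )
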