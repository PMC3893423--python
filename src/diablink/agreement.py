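"""Agreement between self-reported diabetes status and criterion standards.

Self-report is cross-tabulated against each administrative criterion in a
2x2 table over the included, non-uncertain participants; uncertain-status
participants are tabulated in a separate (positive, negative) row and never
enter the 2x2 statistics.  From a table with cells

======================  ==================  ==================
                        criterion positive  criterion negative
self-report diabetes    a (tp)              b (fp)
self-report non-diab.   c (fn)              d (tn)
======================  ==================  ==================

the statistics are

* sensitivity = a / (a + c)
* specificity = d / (b + d)
* PPV = a / (a + b),  NPV = d / (c + d)
* observed agreement  p_o = (a + d) / N
* chance agreement    p_e = [(a+b)(a+c) + (c+d)(b+d)] / N^2
* kappa = (p_o - p_e) / (1 - p_e)

Kappa is the two-rater Fleiss formula for a dichotomous trait, which for
two raters coincides with Cohen's kappa computed from the marginals; no
continuity correction is applied.  Any statistic with a zero denominator
is reported as nan (undefined), never 0.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .records import (
    AgreementStats,
    ConfusionTable,
    CriterionResult,
    PhenotypeAssignment,
    nan_if_zero_denominator,
)

ALGORITHM_TYPES = ("type1", "type2", "gestational_other")
APDC_TYPE_COLUMNS = (
    "type1",
    "type2",
    "gestational_other",
    "unspecified",
    "no_diabetes_code",
)


def build_confusion(
    assignments: list[PhenotypeAssignment],
    criteria: dict[str, CriterionResult],
) -> tuple[ConfusionTable, tuple[int, int]]:
    """Cross-tabulate assignments against one source's criterion results.

    Only participants included in the source's analysis subset are counted.
    Returns the 2x2 table plus the (criterion-positive, criterion-negative)
    counts among uncertain-status participants.
    """
    tp = fp = fn = tn = 0
    unc_pos = unc_neg = 0
    for a in assignments:
        crit = criteria.get(a.participant_id)
        if crit is None or not crit.included:
            continue
        positive = bool(crit.criterion_positive)
        if a.status == "uncertain":
            if positive:
                unc_pos += 1
            else:
                unc_neg += 1
        elif a.status == "diabetes":
            if positive:
                tp += 1
            else:
                fp += 1
        else:
            if positive:
                fn += 1
            else:
                tn += 1
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn), (unc_pos, unc_neg)


def stats_from_table(table: ConfusionTable) -> AgreementStats:
    """Sensitivity, specificity, PPV, NPV and kappa from a 2x2 table."""
    if table.total == 0:
        raise ValueError("cannot compute agreement statistics on an empty table")
    n = table.total
    p_o = (table.tp + table.tn) / n
    p_e = (
        table.self_report_positive_total * table.criterion_positive_total
        + table.self_report_negative_total * table.criterion_negative_total
    ) / (n * n)
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else math.nan
    return AgreementStats(
        sensitivity=nan_if_zero_denominator(table.tp, table.criterion_positive_total),
        specificity=nan_if_zero_denominator(table.tn, table.criterion_negative_total),
        ppv=nan_if_zero_denominator(table.tp, table.self_report_positive_total),
        npv=nan_if_zero_denominator(table.tn, table.self_report_negative_total),
        observed_agreement=p_o,
        expected_agreement=p_e,
        kappa=kappa,
    )


@dataclass(frozen=True)
class ValidationResult:
    """One source's validation block: table, uncertain row, statistics."""

    source: str
    label: str
    table: ConfusionTable
    uncertain_row: tuple[int, int]
    stats: AgreementStats


def validate_source(
    source: str,
    label: str,
    assignments: list[PhenotypeAssignment],
    criteria: dict[str, CriterionResult],
) -> ValidationResult:
    table, uncertain = build_confusion(assignments, criteria)
    return ValidationResult(source, label, table, uncertain, stats_from_table(table))


@dataclass(frozen=True)
class TypeCrosstab:
    """Algorithm type vs hospital-coded type for the admitted diabetes group.

    ``counts`` is a 3x5 table (rows: algorithm type1/type2/gestational_other;
    columns: hospital type1/type2/gestational_other/unspecified/
    no_diabetes_code).  ``row_agreement`` is the diagonal cell over the row
    total for the three concordant columns (nan for an empty row).
    """

    counts: pd.DataFrame

    @property
    def row_agreement(self) -> pd.Series:
        diag = pd.Series(
            [self.counts.at[t, t] for t in ALGORITHM_TYPES], index=ALGORITHM_TYPES
        )
        totals = self.counts.sum(axis=1)
        return diag.where(totals > 0).div(totals.where(totals > 0)).astype(float)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def type_crosstab(
    typed_assignments: list[PhenotypeAssignment],
    criteria: dict[str, CriterionResult],
) -> TypeCrosstab:
    """Tabulate algorithm type against hospital-coded type.

    Restricted to diabetes-group participants included in the hospital-data
    analysis subset.
    """
    tally: Counter[tuple[str, str]] = Counter()
    for a in typed_assignments:
        if a.status != "diabetes":
            continue
        crit = criteria.get(a.participant_id)
        if crit is None or not crit.included:
            continue
        tally[(a.diabetes_type, crit.apdc_type)] += 1
    counts = pd.DataFrame(
        [[tally[(row, col)] for col in APDC_TYPE_COLUMNS] for row in ALGORITHM_TYPES],
        index=list(ALGORITHM_TYPES),
        columns=list(APDC_TYPE_COLUMNS),
        dtype=int,
    )
    return TypeCrosstab(counts=counts)


def crosstab_from_counts(counts: dict[str, dict[str, int]]) -> TypeCrosstab:
    """Build a :class:`TypeCrosstab` from an explicit count matrix
    (rows: algorithm type; columns: hospital-coded type)."""
    df = pd.DataFrame(
        0, index=list(ALGORITHM_TYPES), columns=list(APDC_TYPE_COLUMNS), dtype=int
    )
    for row, cols in counts.items():
        for col, value in cols.items():
            df.at[row, col] = value
    return TypeCrosstab(counts=df)
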