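"""Published agreement tables from the 45 and Up Study diabetes validation.

The original validation of self-reported diabetes in the 45 and Up cohort
(266,848 NSW residents aged 45+, recruited 2006-2009, linked to hospital,
medical-service and pharmacy claims collections) published its 2x2
cross-tabulations, the uncertain-group counts, the type-agreement matrix
and the phenotyping component counts.  Those printed counts are packaged
here so the agreement statistics can be recomputed from them; the
underlying unit-record data are access-restricted and are not reproduced
or reproducible by this package.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import ConfusionTable


@dataclass(frozen=True)
class PublishedValidationTable:
    source: str
    label: str
    table: ConfusionTable
    uncertain_row: tuple[int, int]


#: Self-report vs at least one hospital diabetes diagnosis code, 2000-2009.
APDC_TABLE = PublishedValidationTable(
    source="apdc",
    label="self-report vs hospital diabetes diagnosis codes (2000-2009)",
    table=ConfusionTable(tp=15_143, fp=3_943, fn=2_904, tn=169_983),
    uncertain_row=(557, 596),
)

#: Self-report vs at least one HbA1c test claim, calendar years 2005-2009.
MBS_TABLE = PublishedValidationTable(
    source="mbs",
    label="self-report vs >=1 HbA1c test claim (2005-2009)",
    table=ConfusionTable(tp=20_340, fp=3_664, fn=11_514, tn=228_157),
    uncertain_row=(787, 590),
)

#: Self-report vs at least one insulin/OHA dispensing claim in the 12 months
#: before recruitment.
PBS_TABLE = PublishedValidationTable(
    source="pbs",
    label="self-report vs >=1 diabetes medication dispensing (12-month lookback)",
    table=ConfusionTable(tp=14_465, fp=5_780, fn=663, tn=191_068),
    uncertain_row=(770, 394),
)

PUBLISHED_TABLES = (APDC_TABLE, MBS_TABLE, PBS_TABLE)

#: Algorithm-assigned type (rows) vs hospital-coded type (columns) for the
#: admitted diabetes group.
TYPE_CROSSTAB_COUNTS: dict[str, dict[str, int]] = {
    "type1": {
        "type1": 314,
        "type2": 383,
        "gestational_other": 2,
        "unspecified": 1,
        "no_diabetes_code": 56,
    },
    "type2": {
        "type1": 451,
        "type2": 13_822,
        "gestational_other": 18,
        "unspecified": 45,
        "no_diabetes_code": 3_664,
    },
    "gestational_other": {
        "type1": 26,
        "type2": 61,
        "gestational_other": 20,
        "unspecified": 0,
        "no_diabetes_code": 223,
    },
}

#: Published evidence-path component counts of the phenotyping algorithm.
PHENOTYPE_COMPONENTS = {
    "cohort_size": 266_848,
    "tickbox": 23_981,
    "free_text_diabetes": 119,
    "insulin_text": 58,
    "free_text_uncertain": 136,
    "oha_only_uncertain": 1_246,
}
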