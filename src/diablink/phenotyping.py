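"""Rule-based assignment of baseline diabetes status from the questionnaire.

Each participant is routed to exactly one of three groups, in a fixed
evaluation order:

1. ticked "Has a doctor EVER told you that you have diabetes?" -> diabetes
   (evidence: tickbox);
2. otherwise, free-text "other illness" box mentions a diabetes-specific
   phrase -> diabetes (free_text), or an uncertainty phrase such as
   "borderline diabetes" or "diabetes insipidus" -> uncertain (free_text);
   uncertainty phrases take precedence over positive phrases;
3. otherwise, the medication fields: a reported insulin product -> diabetes
   (insulin_text); an oral hypoglycaemic agent only -> uncertain (oha_text);
4. otherwise non-diabetes.

Matching is case-insensitive, whitespace-normalised, whole-phrase with
word boundaries, driven by two editable CSV lexicons (the packaged defaults
cover the common Australian insulin/OHA brand and generic names and the
diagnosis phrasings above).  There is no spelling correction: misspellings
are handled only by adding lexicon variants.  Incident (post-recruitment)
cases are deliberately not sought.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .records import (
    MEDICATION_CLASSES,
    OHA_CLASSES,
    PhenotypeAssignment,
    QuestionnaireRecord,
)

# Word-boundary matching that also treats hyphens/punctuation as boundaries:
# "diabetes" must not match inside "diabetic", but may match inside
# "pre-diabetes" (which the uncertainty list intercepts first).
def _compile_phrase(term: str) -> re.Pattern[str]:
    tokens = [re.escape(tok) for tok in term.lower().split()]
    return re.compile(r"(?<!\w)" + r"\s+".join(tokens) + r"(?!\w)")


def _normalise(text: str) -> str:
    return " ".join(text.lower().split())


@dataclass(frozen=True)
class MedicationLexicon:
    """Mapping from lower-cased product/keyword to medication class."""

    entries: dict[str, str]
    _patterns: dict[str, re.Pattern[str]] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        cleaned: dict[str, str] = {}
        for term, cls in self.entries.items():
            key = _normalise(term)
            if key in cleaned and cleaned[key] != cls:
                raise ValueError(f"duplicate lexicon term {key!r} with conflicting class")
            if cls not in MEDICATION_CLASSES:
                raise ValueError(f"lexicon term {key!r} has unknown class {cls!r}")
            cleaned[key] = cls
        for required, req_class in (
            ("diabex", "biguanide"),
            ("diaformin", "biguanide"),
            ("metformin", "biguanide"),
            ("insulin", "insulin"),
        ):
            if cleaned.get(required) != req_class:
                raise ValueError(
                    f"lexicon must map {required!r} to {req_class!r}"
                )
        object.__setattr__(self, "entries", cleaned)
        object.__setattr__(
            self, "_patterns", {t: _compile_phrase(t) for t in cleaned}
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "MedicationLexicon":
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
        return cls({row["term"]: row["class"] for row in rows})

    @classmethod
    def default(cls) -> "MedicationLexicon":
        ref = resources.files("diablink").joinpath("data/medication_lexicon.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def matches(self, text: str) -> set[str]:
        """All lexicon terms that occur in ``text`` (normalised)."""
        norm = _normalise(text)
        if not norm:
            return set()
        return {t for t, pat in self._patterns.items() if pat.search(norm)}


@dataclass(frozen=True)
class DiagnosisLexicon:
    """Free-text diagnosis phrases.

    ``uncertain_terms`` (pre-diabetes, borderline diabetes, diabetes
    insipidus, ...) take precedence over ``positive_terms`` at
    classification time, so "diabetes insipidus" is routed to uncertain
    even though it contains the positive phrase "diabetes".
    """

    positive_terms: tuple[str, ...]
    uncertain_terms: tuple[str, ...]
    _positive: tuple[re.Pattern[str], ...] = field(init=False, repr=False, compare=False)
    _uncertain: tuple[re.Pattern[str], ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        pos = tuple(_normalise(t) for t in self.positive_terms)
        unc = tuple(_normalise(t) for t in self.uncertain_terms)
        overlap = set(pos) & set(unc)
        if overlap:
            raise ValueError(f"terms in both positive and uncertain lists: {overlap}")
        object.__setattr__(self, "positive_terms", pos)
        object.__setattr__(self, "uncertain_terms", unc)
        object.__setattr__(self, "_positive", tuple(_compile_phrase(t) for t in pos))
        object.__setattr__(self, "_uncertain", tuple(_compile_phrase(t) for t in unc))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DiagnosisLexicon":
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
        return cls(
            positive_terms=tuple(r["term"] for r in rows if r["category"] == "positive"),
            uncertain_terms=tuple(r["term"] for r in rows if r["category"] == "uncertain"),
        )

    @classmethod
    def default(cls) -> "DiagnosisLexicon":
        ref = resources.files("diablink").joinpath("data/diagnosis_lexicon.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


@dataclass(frozen=True)
class Lexicons:
    diagnosis: DiagnosisLexicon
    medication: MedicationLexicon

    @classmethod
    def default(cls) -> "Lexicons":
        return cls(DiagnosisLexicon.default(), MedicationLexicon.default())

    @classmethod
    def from_dir(cls, directory: str | Path) -> "Lexicons":
        directory = Path(directory)
        return cls(
            DiagnosisLexicon.from_csv(directory / "diagnosis_lexicon.csv"),
            MedicationLexicon.from_csv(directory / "medication_lexicon.csv"),
        )


def match_free_text_diagnosis(text: str, lexicon: DiagnosisLexicon) -> str:
    """Classify a free-text illness entry: 'uncertain', 'diabetes' or 'none'.

    Uncertainty phrases are checked first and win over positive phrases.
    """
    norm = _normalise(text)
    if not norm:
        return "none"
    if any(p.search(norm) for p in lexicon._uncertain):
        return "uncertain"
    if any(p.search(norm) for p in lexicon._positive):
        return "diabetes"
    return "none"


def match_medication_text(
    text: str, metformin_tickbox: bool, lexicon: MedicationLexicon
) -> tuple[bool, bool, set[str]]:
    """Scan the medication free text for insulin and OHA products.

    Returns ``(insulin_flag, oha_flag, matched_classes)``.  The dedicated
    Diabex/Diaformin/Metformin tick box sets the OHA flag (class biguanide)
    even when the text box is empty.
    """
    matched_classes = {lexicon.entries[t] for t in lexicon.matches(text)}
    matched_classes.discard("non_diabetes")
    if metformin_tickbox:
        matched_classes.add("biguanide")
    insulin_flag = "insulin" in matched_classes
    oha_flag = any(c in OHA_CLASSES for c in matched_classes)
    return insulin_flag, oha_flag, matched_classes


def assign_status(
    record: QuestionnaireRecord, lexicons: Lexicons
) -> PhenotypeAssignment:
    """Assign one participant's diabetes status (see module docstring).

    Self-reported insulin/OHA use is recorded for every participant
    regardless of which rule determined the status, because the typing
    algorithm and the pharmacy comparison use it for all groups.
    """
    insulin_flag, oha_flag, _ = match_medication_text(
        record.medication_text, record.metformin_tickbox, lexicons.medication
    )
    if record.diabetes_tickbox:
        status, evidence = "diabetes", "tickbox"
    else:
        text_result = match_free_text_diagnosis(
            record.other_illness_text, lexicons.diagnosis
        )
        if text_result == "diabetes":
            status, evidence = "diabetes", "free_text"
        elif text_result == "uncertain":
            status, evidence = "uncertain", "free_text"
        elif insulin_flag:
            status, evidence = "diabetes", "insulin_text"
        elif oha_flag:
            status, evidence = "uncertain", "oha_text"
        else:
            status, evidence = "non_diabetes", "none"
    return PhenotypeAssignment(
        participant_id=record.participant_id,
        status=status,
        evidence=evidence,
        self_reported_insulin=insulin_flag,
        self_reported_oha=oha_flag,
    )


@dataclass(frozen=True)
class PhenotypeCounts:
    """Stage accounting for a phenotyped cohort.

    The free-text-uncertain and OHA-only groups are disjoint by
    construction (the free-text rule fires first), so their union is the
    sum; both are reported separately alongside the union.
    """

    cohort_size: int
    tickbox: int
    free_text_diabetes: int
    insulin_text: int
    free_text_uncertain: int
    oha_only_uncertain: int
    non_diabetes: int

    @property
    def diabetes_total(self) -> int:
        return self.tickbox + self.free_text_diabetes + self.insulin_text

    @property
    def uncertain_total(self) -> int:
        return self.free_text_uncertain + self.oha_only_uncertain

    @property
    def prevalence(self) -> float:
        """Reported diabetes prevalence; nan (undefined) on an empty cohort."""
        if self.cohort_size == 0:
            return math.nan
        return self.diabetes_total / self.cohort_size


def phenotype_cohort(
    records: list[QuestionnaireRecord], lexicons: Lexicons | None = None
) -> tuple[list[PhenotypeAssignment], PhenotypeCounts]:
    """Assign status to every participant and tally the evidence paths."""
    if lexicons is None:
        lexicons = Lexicons.default()
    assignments = [assign_status(r, lexicons) for r in records]
    tally = {("diabetes", "tickbox"): 0, ("diabetes", "free_text"): 0,
             ("diabetes", "insulin_text"): 0, ("uncertain", "free_text"): 0,
             ("uncertain", "oha_text"): 0, ("non_diabetes", "none"): 0}
    for a in assignments:
        tally[(a.status, a.evidence)] += 1
    counts = PhenotypeCounts(
        cohort_size=len(records),
        tickbox=tally[("diabetes", "tickbox")],
        free_text_diabetes=tally[("diabetes", "free_text")],
        insulin_text=tally[("diabetes", "insulin_text")],
        free_text_uncertain=tally[("uncertain", "free_text")],
        oha_only_uncertain=tally[("uncertain", "oha_text")],
        non_diabetes=tally[("non_diabetes", "none")],
    )
    return assignments, counts
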