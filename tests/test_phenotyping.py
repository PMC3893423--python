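import math

import pytest
from hypothesis import given, strategies as st

from diablink.phenotyping import (
    DiagnosisLexicon,
    Lexicons,
    MedicationLexicon,
    assign_status,
    match_free_text_diagnosis,
    match_medication_text,
    phenotype_cohort,
)
from diablink.simulate import GeneratorParams, generate

from conftest import make_record


@pytest.mark.parametrize(
    ("text", "expected"),
    [
        ("sugar diabetes", "diabetes"),
        ("diabetes", "diabetes"),
        ("Type 2 Diabetes", "diabetes"),
        ("diabetes insipidus", "uncertain"),
        ("borderline diabetes", "uncertain"),
        ("pre-diabetes", "uncertain"),
        ("", "none"),
        ("hypertension", "none"),
        ("diabetic", "none"),  # word boundary: no whole-phrase match
        ("asthma, sugar diabetes, gout", "diabetes"),
    ],
)
def test_free_text_diagnosis_matching(text, expected, lexicons):
    assert match_free_text_diagnosis(text, lexicons.diagnosis) == expected


@pytest.mark.parametrize(
    ("text", "met_tick", "insulin", "oha", "classes"),
    [
        ("", True, False, True, {"biguanide"}),
        ("insulin twice daily", False, True, False, {"insulin"}),
        ("", False, False, False, set()),
        ("Lantus and metformin", False, True, True, {"insulin", "biguanide"}),
        ("atenolol", False, False, False, set()),
        ("gliclazide", False, False, True, {"sulphonylurea"}),
    ],
)
def test_medication_text_matching(text, met_tick, insulin, oha, classes, lexicons):
    assert match_medication_text(text, met_tick, lexicons.medication) == (
        insulin,
        oha,
        classes,
    )


@pytest.mark.parametrize(
    ("record", "status", "evidence"),
    [
        # tick box wins over uncertain free text
        (make_record(tick=True, illness="borderline diabetes"), "diabetes", "tickbox"),
        # insulin-only medication report joins the diabetes group
        (make_record(meds="insulin twice daily"), "diabetes", "insulin_text"),
        # metformin tick alone is OHA-only -> uncertain
        (make_record(met_tick=True), "uncertain", "oha_text"),
        # positive free text without the tick box
        (make_record(illness="sugar diabetes"), "diabetes", "free_text"),
        # uncertain free text beats an insulin mention in the medication box
        (make_record(illness="diabetes insipidus", meds="insulin"), "uncertain", "free_text"),
        # nothing reported
        (make_record(), "non_diabetes", "none"),
    ],
)
def test_status_assignment_paths(record, status, evidence, lexicons):
    a = assign_status(record, lexicons)
    assert (a.status, a.evidence) == (status, evidence)
    assert not a.problems()


def test_medication_flags_recorded_on_every_path(lexicons):
    a = assign_status(make_record(tick=True, meds="lantus, metformin"), lexicons)
    assert a.self_reported_insulin and a.self_reported_oha
    b = assign_status(make_record(illness="diabetes insipidus", meds="insulin"), lexicons)
    assert b.self_reported_insulin and b.status == "uncertain"


@given(
    positive=st.sampled_from(
        ("diabetes", "sugar diabetes", "diabetes type 2", "grade 2 diabetes")
    ),
    uncertain=st.sampled_from(
        ("pre-diabetes", "borderline diabetes", "diabetes insipidus")
    ),
    order=st.booleans(),
)
def test_uncertain_terms_take_precedence(positive, uncertain, order, lexicons):
    """Any text matching both an uncertainty and a positive phrase is uncertain."""
    text = f"{positive} and {uncertain}" if order else f"{uncertain}, {positive}"
    assert match_free_text_diagnosis(text, lexicons.diagnosis) == "uncertain"


def test_adding_uncertain_terms_never_promotes_to_diabetes(lexicons):
    records = [
        make_record(pid="A", illness="sugar diabetes"),
        make_record(pid="B", illness="diabetes insipidus"),
        make_record(pid="C", illness="controlled diabetes"),
        make_record(pid="D"),
    ]
    base, _ = phenotype_cohort(records, lexicons)
    extended = Lexicons(
        DiagnosisLexicon(
            positive_terms=tuple(
                t for t in lexicons.diagnosis.positive_terms if t != "sugar diabetes"
            ),
            uncertain_terms=lexicons.diagnosis.uncertain_terms + ("sugar diabetes",),
        ),
        lexicons.medication,
    )
    after, _ = phenotype_cohort(records, extended)
    for before_a, after_a in zip(base, after):
        if before_a.status == "uncertain":
            assert after_a.status != "diabetes"


def test_assignment_is_deterministic(lexicons):
    records = [make_record(pid=f"P{i}", illness="diabetes" if i % 3 == 0 else "",
                           meds="metformin" if i % 5 == 0 else "")
               for i in range(60)]
    first, _ = phenotype_cohort(records, lexicons)
    second, _ = phenotype_cohort(records, lexicons)
    assert first == second


def test_statuses_partition_the_cohort(small_cohort, lexicons):
    _, bundle, _ = small_cohort
    assignments, counts = phenotype_cohort(bundle.questionnaires, lexicons)
    assert len(assignments) == bundle.n
    assert all(a.status in ("diabetes", "non_diabetes", "uncertain") for a in assignments)
    assert (
        counts.diabetes_total + counts.uncertain_total + counts.non_diabetes
        == counts.cohort_size
    )
    assert counts.uncertain_total == counts.free_text_uncertain + counts.oha_only_uncertain


def test_empty_cohort_has_undefined_prevalence(lexicons):
    assignments, counts = phenotype_cohort([], lexicons)
    assert assignments == []
    assert math.isnan(counts.prevalence)


def test_pure_tickbox_generator_yields_only_tickbox_evidence(lexicons):
    """With perfect tick-box response and no free-text/medication-only
    reporters, every diabetes assignment enters via the tick box."""
    params = GeneratorParams(
        n=2_000, seed=5, tick_sens=1.0, tick_spec=1.0, free_text_rate=0.0,
        uncertain_text_rate=0.0, insulin_given_type1=0.0, insulin_given_type2=0.0,
        oha_given_diabetes=0.0,
    )
    bundle, truth = generate(params)
    assignments, counts = phenotype_cohort(bundle.questionnaires, lexicons)
    diabetics = [a for a in assignments if a.status == "diabetes"]
    assert diabetics and all(a.evidence == "tickbox" for a in diabetics)
    assert counts.diabetes_total == int(truth["true_diabetes"].sum())


def test_medication_lexicon_requires_tickbox_products():
    with pytest.raises(ValueError, match="metformin"):
        MedicationLexicon({"insulin": "insulin", "diabex": "biguanide",
                           "diaformin": "biguanide"})
    with pytest.raises(ValueError, match="unknown class"):
        MedicationLexicon({"insulin": "insulin", "diabex": "biguanide",
                           "diaformin": "biguanide", "metformin": "biguanide",
                           "foo": "bar"})


def test_diagnosis_lexicon_lists_must_be_disjoint():
    with pytest.raises(ValueError, match="both"):
        DiagnosisLexicon(positive_terms=("diabetes",), uncertain_terms=("diabetes",))
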