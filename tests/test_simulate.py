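import math

import pytest

from diablink import io
from diablink.phenotyping import phenotype_cohort
from diablink.simulate import (
    GeneratorParams,
    default_window_config,
    expected_cells,
    expected_stats,
    generate,
)


def test_same_seed_gives_byte_identical_files(tmp_path):
    params = GeneratorParams(n=250, seed=8)
    for sub in ("one", "two"):
        bundle, truth = generate(params)
        out = tmp_path / sub
        io.write_cohort(bundle, out)
        truth.to_csv(out / "truth.csv", index=False)
    for name in list(io.COHORT_FILES.values()) + ["truth.csv"]:
        assert (tmp_path / "one" / name).read_bytes() == (tmp_path / "two" / name).read_bytes()


def test_different_seeds_differ():
    a, _ = generate(GeneratorParams(n=100, seed=1))
    b, _ = generate(GeneratorParams(n=100, seed=2))
    assert a.questionnaires != b.questionnaires


def test_enlarging_cohort_preserves_early_participants():
    small, truth_small = generate(GeneratorParams(n=40, seed=6))
    big, truth_big = generate(GeneratorParams(n=90, seed=6))
    assert big.questionnaires[:40] == small.questionnaires
    assert truth_big.iloc[:40].equals(truth_small.iloc[:40])


def test_generated_records_satisfy_invariants(small_cohort):
    _, bundle, truth = small_cohort
    assert len({q.participant_id for q in bundle.questionnaires}) == bundle.n
    for collection in (bundle.questionnaires, bundle.admissions,
                       bundle.mbs_claims, bundle.pbs_claims):
        for record in collection:
            assert not record.problems()
    assert len(truth) == bundle.n


def test_zero_prevalence_degenerate_case():
    params = GeneratorParams(n=1_500, seed=13, prevalence=0.0)
    bundle, truth = generate(params)
    assert not truth["true_diabetes"].any()
    assignments, counts = phenotype_cohort(bundle.questionnaires)
    # diabetes can only arise from spurious tick-box responses
    for a in assignments:
        if a.status == "diabetes":
            assert a.evidence == "tickbox"
    assert counts.diabetes_total <= counts.cohort_size * (1 - params.tick_spec) * 10 + 10


@pytest.mark.parametrize(
    ("field", "value"),
    [("prevalence", 1.5), ("tick_sens", -0.1), ("n", 0), ("hba1c_rate_diabetes", -1.0)],
)
def test_invalid_params_name_the_parameter(field, value):
    with pytest.raises(ValueError, match=field):
        GeneratorParams(**{field: value}).validate()


def test_noiseless_limit_gives_perfect_expected_stats():
    params = GeneratorParams(
        tick_sens=1.0, tick_spec=1.0, code_sens=1.0, code_spec=1.0,
        hba1c_rate_diabetes=100.0, hba1c_rate_other=0.0,
        pbs_claim_sens=1.0, pbs_claim_fpr=0.0,
    )
    for source in ("apdc", "mbs", "pbs"):
        s = expected_stats(params, source)
        assert s.sensitivity == pytest.approx(1.0)
        assert s.specificity == pytest.approx(1.0)
        assert s.ppv == pytest.approx(1.0)
        assert s.npv == pytest.approx(1.0)
        assert s.kappa == pytest.approx(1.0)


def test_single_noise_source_identity():
    """With a perfect criterion and no other self-report routes, the expected
    sensitivity of self-report equals the tick-box sensitivity."""
    s = 0.8
    params = GeneratorParams(
        tick_sens=s, tick_spec=1.0, code_sens=1.0, code_spec=1.0,
        free_text_rate=0.0, insulin_given_type1=0.0, insulin_given_type2=0.0,
        oha_given_diabetes=0.0, age_dx_missing_rate=1.0,
    )
    assert expected_stats(params, "apdc").sensitivity == pytest.approx(s)


def test_expected_cells_are_a_distribution():
    cells = expected_cells(GeneratorParams(), "apdc")
    assert sum(cells.values()) == pytest.approx(1.0)
    assert all(v >= 0 for v in cells.values())


def test_closed_form_refuses_gestational_codes():
    with pytest.raises(ValueError, match="gestational"):
        expected_cells(GeneratorParams(gdm_code_prob=0.1), "apdc")


def test_uncertain_paths_route_to_uncertain():
    """Diabetics generated as OHA-only reporters all land in the uncertain
    group (cross-module consistency of generator and phenotyping)."""
    params = GeneratorParams(
        n=1_200, seed=21, tick_sens=0.0, tick_spec=1.0, free_text_rate=0.0,
        insulin_given_type1=0.0, insulin_given_type2=0.0, oha_given_diabetes=1.0,
        uncertain_text_rate=0.0,
    )
    bundle, truth = generate(params)
    assignments, counts = phenotype_cohort(bundle.questionnaires)
    diabetic_ids = set(truth.loc[truth["true_diabetes"], "participant_id"])
    for a in assignments:
        if a.participant_id in diabetic_ids:
            assert a.status == "uncertain" and a.evidence == "oha_text"
    assert counts.oha_only_uncertain == len(diabetic_ids)


def test_monte_carlo_matches_closed_form(large_run):
    """Pipeline statistics on a large generated cohort agree with the
    analytic expectations within three binomial standard errors."""
    params, _, _, result, _ = large_run
    for source in ("apdc", "mbs", "pbs"):
        observed = result.validation(source)
        expected = expected_stats(params, source)
        t = observed.table
        for name, denom in (("sensitivity", t.tp + t.fn), ("specificity", t.fp + t.tn),
                            ("ppv", t.tp + t.fp), ("npv", t.fn + t.tn)):
            exp = getattr(expected, name)
            obs = getattr(observed.stats, name)
            se = math.sqrt(exp * (1 - exp) / denom)
            assert abs(obs - exp) < 3 * se, (source, name, obs, exp, se)


def test_parameter_recovery_from_pipeline_output(large_run):
    """Inverting the closed-form relations on pipeline output recovers the
    generating prevalence and tick-box sensitivity."""
    params, bundle, _, result, _ = large_run
    from scipy.stats import poisson

    # prevalence from the HbA1c criterion margin (inclusion there is
    # independent of status under the generator)
    cfg = default_window_config(params)
    n_years = cfg.hba1c_year_end - cfg.hba1c_year_start + 1
    q_d = poisson.sf(cfg.hba1c_min_claims - 1, n_years * params.hba1c_rate_diabetes)
    q_nd = poisson.sf(cfg.hba1c_min_claims - 1, n_years * params.hba1c_rate_other)
    mbs = result.criteria["mbs"]
    included = [r for r in mbs.values() if r.included]
    n_inc = len(included)
    p_pos = sum(1 for r in included if r.criterion_positive) / n_inc
    prev_hat = (p_pos - q_nd) / (q_d - q_nd)
    se_prev = math.sqrt(p_pos * (1 - p_pos) / n_inc) / (q_d - q_nd)
    assert abs(prev_hat - params.prevalence) < 3 * se_prev

    # tick-box sensitivity from the tick-box route share
    n = result.phenotype_counts.cohort_size
    p_tick = result.phenotype_counts.tickbox / n
    ts_hat = (p_tick - (1 - params.prevalence) * (1 - params.tick_spec)) / params.prevalence
    se_ts = math.sqrt(p_tick * (1 - p_tick) / n) / params.prevalence
    assert abs(ts_hat - params.tick_sens) < 3 * se_ts
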