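import datetime as dt
import itertools

import pytest

from diablink.criteria import (
    apdc_criteria,
    apdc_criterion,
    apdc_type,
    diagnosis_year,
    mbs_criterion,
    pbs_criterion,
)
from diablink.records import (
    AdmissionRecord,
    LinkageStatus,
    MbsClaim,
    PbsClaim,
    WindowConfig,
)
from diablink.simulate import GeneratorParams, default_window_config, generate

from conftest import make_record

CFG = WindowConfig()
LINKED = LinkageStatus("P1", True, True)
UNLINKED = LinkageStatus("P1", False, False)


def adm(codes, date=dt.date(2005, 6, 1), pid="P1"):
    return AdmissionRecord(pid, date, tuple(codes))


# ---------------------------------------------------------------------------
# hospital (APDC) criterion
# ---------------------------------------------------------------------------


def test_diabetes_code_in_additional_position_is_positive():
    r = apdc_criterion(make_record(), [adm(["I21.0", "E11.9"])], LINKED, CFG)
    assert r.included and r.criterion_positive


def test_admission_without_diabetes_codes_is_negative():
    r = apdc_criterion(make_record(), [adm(["I21.0"])], LINKED, CFG)
    assert r.included and not r.criterion_positive


def test_unlinked_participant_is_excluded():
    r = apdc_criterion(make_record(), [adm(["E11.9"])], UNLINKED, CFG)
    assert not r.included and r.exclusion_reason == "not_linked"
    assert r.criterion_positive is None


def test_no_admission_in_window_is_excluded():
    r = apdc_criterion(make_record(), [], LINKED, CFG)
    assert r.exclusion_reason == "no_admission"
    # an admission before the window start does not count
    r = apdc_criterion(
        make_record(), [adm(["E11.9"], date=dt.date(2000, 3, 1))], LINKED, CFG
    )
    assert r.exclusion_reason == "no_admission"


def test_diagnosis_after_last_admission_is_excluded():
    # born 1950, diagnosed at 57 -> 2007; last admission 2005
    record = make_record(tick=True, age_dx=57)
    r = apdc_criterion(record, [adm(["E11.9"])], LINKED, CFG)
    assert r.exclusion_reason == "diagnosed_after_last_admission"
    # a later admission rescues the participant (year comparison)
    r = apdc_criterion(
        record,
        [adm(["E11.9"]), adm(["I10"], date=dt.date(2007, 2, 1))],
        LINKED,
        CFG,
    )
    assert r.included


def test_gestational_only_codes_are_excluded():
    record = make_record(sex="female")
    r = apdc_criterion(record, [adm(["O24.1", "I10"])], LINKED, CFG)
    assert r.exclusion_reason == "gestational_only"
    # a non-gestational diabetes code alongside keeps the participant in
    r = apdc_criterion(record, [adm(["O24.1", "E11.9"])], LINKED, CFG)
    assert r.included and r.criterion_positive


def test_diagnosis_year_from_age():
    assert diagnosis_year(make_record(yob=1950, tick=True, age_dx=30)) == 1980
    assert diagnosis_year(make_record()) is None


_CODE_POOL = ("E10.9", "E11.3", "E13.1", "O24.2", "E14", "I21.0")


def _oracle_type(codes):
    """Independent precedence enumeration for hospital-coded type."""
    families = {c.split(".")[0] for c in codes}
    if "E10" in families:
        return "type1"
    if "E11" in families:
        return "type2"
    if "E13" in families or "O24" in families:
        return "gestational_other"
    if "E14" in families:
        return "unspecified"
    return "no_diabetes_code"


@pytest.mark.parametrize(
    "subset",
    [c for n in range(len(_CODE_POOL) + 1) for c in itertools.combinations(_CODE_POOL, n)],
)
def test_apdc_type_precedence_exhaustive(subset):
    codes = subset if subset else ("I10",)
    # spread the codes over two admissions to check cross-admission pooling
    admissions = [adm(codes[: len(codes) // 2 + 1]), adm(codes[len(codes) // 2 + 1 :] or ("I10",))]
    assert apdc_type(admissions) == _oracle_type(subset)


def test_type1_code_implies_positive_criterion(small_cohort):
    _, bundle, _ = small_cohort
    for r in apdc_criteria(bundle).values():
        if r.apdc_type == "type1":
            assert r.criterion_positive


# ---------------------------------------------------------------------------
# HbA1c claims (MBS) criterion
# ---------------------------------------------------------------------------


def claim(year, item=66551, pid="P1"):
    return MbsClaim(pid, dt.date(year, 5, 10), item)


def test_single_claim_meets_threshold_one():
    r = mbs_criterion(make_record(), [claim(2006)], LINKED, CFG)
    assert r.included and r.criterion_positive


def test_single_claim_fails_threshold_two():
    cfg2 = WindowConfig(hba1c_min_claims=2)
    r = mbs_criterion(make_record(), [claim(2006)], LINKED, cfg2)
    assert r.included and not r.criterion_positive
    r = mbs_criterion(make_record(), [claim(2006), claim(2008)], LINKED, cfg2)
    assert r.criterion_positive


def test_claim_before_counting_window_is_ignored():
    # extraction began in 2004 but counting starts in 2005
    r = mbs_criterion(make_record(), [claim(2004)], LINKED, CFG)
    assert r.included and not r.criterion_positive


def test_non_hba1c_items_do_not_count():
    r = mbs_criterion(make_record(), [claim(2006, item=23)], LINKED, CFG)
    assert not r.criterion_positive


def test_mbs_exclusions():
    r = mbs_criterion(make_record(), [claim(2006)], UNLINKED, CFG)
    assert r.exclusion_reason == "not_linked"
    # born 1950, diagnosed at 58 -> 2008, after a window ending in 2007
    cfg_short = WindowConfig(hba1c_year_start=2005, hba1c_year_end=2007)
    r = mbs_criterion(make_record(tick=True, age_dx=58),
                      [claim(2006)], LINKED, cfg_short)
    assert r.exclusion_reason == "diagnosis_after_window"


# ---------------------------------------------------------------------------
# dispensing (PBS) criterion
# ---------------------------------------------------------------------------


def rx(days_before, cls="insulin", pid="P1", recruit=dt.date(2008, 6, 1)):
    return PbsClaim(pid, recruit - dt.timedelta(days=days_before), cls)


def test_insulin_claim_in_lookback_is_positive():
    r = pbs_criterion(make_record(), [rx(30)], LINKED, CFG)
    assert r.included and r.criterion_positive


def test_statin_only_claims_are_negative_but_included():
    r = pbs_criterion(make_record(), [rx(30, cls="non_diabetes")], LINKED, CFG)
    assert r.included and not r.criterion_positive


def test_dva_card_holders_are_excluded():
    r = pbs_criterion(make_record(dva=True), [rx(30)], LINKED, CFG)
    assert r.exclusion_reason == "dva_card"


def test_no_claims_in_lookback_is_excluded():
    r = pbs_criterion(make_record(), [], LINKED, CFG)
    assert r.exclusion_reason == "no_pbs_claims"
    # a claim older than the lookback does not qualify
    r = pbs_criterion(make_record(), [rx(400)], LINKED, CFG)
    assert r.exclusion_reason == "no_pbs_claims"


def test_claim_on_recruitment_day_is_not_prior():
    r = pbs_criterion(make_record(), [rx(0)], LINKED, CFG)
    assert r.exclusion_reason == "no_pbs_claims"


def test_oha_claim_counts_as_diabetes_medication():
    r = pbs_criterion(make_record(), [rx(100, cls="sulphonylurea")], LINKED, CFG)
    assert r.criterion_positive


# ---------------------------------------------------------------------------
# cohort-level invariants
# ---------------------------------------------------------------------------


def test_included_plus_excluded_covers_cohort(small_cohort):
    params, bundle, _ = small_cohort
    cfg = default_window_config(params)
    from diablink.criteria import all_criteria

    for source, results in all_criteria(bundle, cfg).items():
        assert len(results) == bundle.n
        n_inc = sum(1 for r in results.values() if r.included)
        n_exc = sum(1 for r in results.values() if not r.included)
        assert n_inc + n_exc == bundle.n
        assert all(not r.problems() for r in results.values())


def test_shrinking_windows_never_creates_positives(small_cohort):
    params, bundle, _ = small_cohort
    wide = default_window_config(params)
    narrow = WindowConfig(
        apdc_start=dt.date(2004, 1, 1),
        apdc_end=dt.date(2007, 12, 31),
        hba1c_year_start=wide.hba1c_year_start + 1,
        hba1c_year_end=wide.hba1c_year_end - 1,
        pbs_lookback_days=180,
    )
    from diablink.criteria import all_criteria

    wide_res = all_criteria(bundle, wide)
    narrow_res = all_criteria(bundle, narrow)
    for source in ("apdc", "mbs", "pbs"):
        for pid, narrow_r in narrow_res[source].items():
            if narrow_r.included and narrow_r.criterion_positive:
                wide_r = wide_res[source][pid]
                assert wide_r.included and wide_r.criterion_positive
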