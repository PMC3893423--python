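import datetime as dt
import time

import pytest
from hypothesis import settings

from diablink.phenotyping import Lexicons
from diablink.pipeline import run_pipeline
from diablink.records import QuestionnaireRecord
from diablink.simulate import GeneratorParams, default_window_config, generate

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


def make_record(
    pid: str = "P1",
    recruit: dt.date = dt.date(2008, 6, 1),
    sex: str = "male",
    yob: int = 1950,
    tick: bool | None = False,
    age_dx: int | None = None,
    illness: str = "",
    met_tick: bool = False,
    meds: str = "",
    dva: bool = False,
    ald: int | None = None,
) -> QuestionnaireRecord:
    """Questionnaire record factory with innocuous defaults."""
    return QuestionnaireRecord(
        participant_id=pid,
        recruitment_date=recruit,
        sex=sex,
        year_of_birth=yob,
        diabetes_tickbox=tick,
        age_at_diagnosis=age_dx,
        other_illness_text=illness,
        metformin_tickbox=met_tick,
        medication_text=meds,
        dva_card=dva,
        age_at_last_delivery=ald,
    )


@pytest.fixture(scope="session")
def lexicons() -> Lexicons:
    return Lexicons.default()


@pytest.fixture(scope="session")
def small_cohort():
    """A 2,000-participant synthetic cohort for structural tests."""
    params = GeneratorParams(n=2_000, seed=11)
    bundle, truth = generate(params)
    return params, bundle, truth


@pytest.fixture(scope="session")
def large_run():
    """A 100,000-participant cohort pushed through the full pipeline,
    with the wall-clock time of the run (generation + pipeline)."""
    params = GeneratorParams(n=100_000, seed=20260926)
    t0 = time.perf_counter()
    bundle, truth = generate(params)
    result = run_pipeline(bundle, default_window_config(params))
    elapsed = time.perf_counter() - t0
    return params, bundle, truth, result, elapsed
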