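"""Synthetic linked-cohort generator with a closed-form statistics oracle.

Real questionnaire/linked-claims cohorts of this kind are access-restricted,
so every pipeline stage is exercised on synthetic data with known ground
truth.  The generator draws, per participant, a true diabetes status and
type, then questionnaire responses, hospital admissions with ICD-10-AM
codes, HbA1c service claims, pharmacy dispensings and linkage flags, each
with configurable misclassification.  The probability model is deliberately
simple — conditional on true status, every recorded signal is independent —
which makes the expected agreement statistics available in closed form
(:func:`expected_stats`) as an independent oracle for the full pipeline.

Randomness uses one seed; per-participant substreams are derived with
``SeedSequence.spawn`` so participant *i*'s records do not change when the
cohort is enlarged.

Date model (discrete, so the oracle can enumerate it exactly):

* recruitment year uniform on 2006-2009; age at recruitment uniform on
  45-84; year of birth = recruitment year - age;
* diabetes diagnosed ``duration`` years before recruitment: for true type 1,
  age at diagnosis uniform on 5-30; for type 2 (and for spurious
  self-reports), duration uniform on 1-20 years;
* admissions: present with ``admit_prob``; count 1 + Poisson(extra);
  admission years uniform on 2000-2009;
* HbA1c claims: Poisson(years x rate) over the 2004-2009 extraction window,
  uniform dates;
* pharmacy: one diabetes-medication dispensing with probability
  ``pbs_claim_sens`` (diabetic) / ``pbs_claim_fpr`` (non-diabetic) in the
  12-month lookback, plus background non-diabetes dispensings.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import (
    AdmissionRecord,
    AgreementStats,
    CohortBundle,
    LinkageStatus,
    MbsClaim,
    PbsClaim,
    QuestionnaireRecord,
    WindowConfig,
)

_POSITIVE_TEXTS_T1 = ("diabetes", "diabetes type 1", "sugar diabetes")
_POSITIVE_TEXTS_T2 = ("diabetes", "diabetes type 2", "sugar diabetes", "controlled diabetes")
_UNCERTAIN_TEXTS = ("borderline diabetes", "pre-diabetes", "diabetes insipidus")
_DECOY_TEXTS = ("hypertension", "asthma", "osteoarthritis", "high cholesterol", "depression")
_DECOY_MEDS = ("atenolol", "simvastatin", "aspirin", "perindopril")
_INSULIN_BRANDS = ("insulin", "lantus", "novorapid", "humalog", "protaphane")
_OHA_BRANDS = ("metformin", "gliclazide", "diamicron", "glipizide", "pioglitazone")
_BACKGROUND_CODES = ("I10", "I21.0", "J18.9", "K35.8", "M17.1", "S72.00", "N39.0", "E78.0")

_PROBABILITY_FIELDS = (
    "prevalence", "type1_fraction", "tick_sens", "tick_spec", "free_text_rate",
    "uncertain_text_rate", "insulin_given_type1", "insulin_given_type2",
    "oha_given_diabetes", "admit_prob", "code_sens", "code_spec",
    "pbs_claim_sens", "pbs_claim_fpr", "dva_prob", "link_prob",
    "age_dx_missing_rate", "female_fraction", "background_claim_prob",
    "oha_via_tickbox", "decoy_text_rate", "decoy_med_rate",
    "pbs_insulin_fraction", "parous_prob", "gdm_code_prob", "old_claim_prob",
)
_RATE_FIELDS = ("hba1c_rate_diabetes", "hba1c_rate_other", "extra_admissions")


@dataclass(frozen=True)
class GeneratorParams:
    """Generator configuration.

    Defaults emulate the margins observed in the study cohort: ~9%
    self-reported prevalence, ~72% of participants with at least one
    admission over ten years, ~84% of admitted diabetics carrying a coded
    diabetes diagnosis, ~71% of diabetics with a medication dispensing in
    the 12 months before recruitment, ~2.4% DVA card holders.
    """

    n: int = 10_000
    seed: int = 0
    prevalence: float = 0.09
    type1_fraction: float = 0.037
    # questionnaire response model
    tick_sens: float = 0.94
    tick_spec: float = 0.999
    free_text_rate: float = 0.08
    uncertain_text_rate: float = 0.0006
    insulin_given_type1: float = 0.95
    insulin_given_type2: float = 0.07
    oha_given_diabetes: float = 0.58
    age_dx_missing_rate: float = 0.05
    # hospital admissions
    admit_prob: float = 0.72
    code_sens: float = 0.84
    code_spec: float = 0.98
    extra_admissions: float = 1.5
    gdm_code_prob: float = 0.0
    # medical-service claims (HbA1c tests per year)
    hba1c_rate_diabetes: float = 0.38
    hba1c_rate_other: float = 0.01
    # pharmacy dispensings
    pbs_claim_sens: float = 0.714
    pbs_claim_fpr: float = 0.0035
    background_claim_prob: float = 0.88
    pbs_insulin_fraction: float = 0.15
    old_claim_prob: float = 0.2
    # demographics / plumbing
    dva_prob: float = 0.024
    link_prob: float = 0.997
    female_fraction: float = 0.54
    parous_prob: float = 0.85
    oha_via_tickbox: float = 0.8
    decoy_text_rate: float = 0.05
    decoy_med_rate: float = 0.3
    # discrete date model
    age_min: int = 45
    age_max: int = 84
    recruit_year_min: int = 2006
    recruit_year_max: int = 2009
    duration_max: int = 20
    type1_dx_age_min: int = 5
    type1_dx_age_max: int = 30
    admission_year_min: int = 2000
    admission_year_max: int = 2009
    mbs_year_min: int = 2004
    mbs_year_max: int = 2009

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("parameter n must be >= 1")
        for name in _PROBABILITY_FIELDS:
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"parameter {name} must be a probability in [0, 1]")
        for name in _RATE_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be >= 0")
        if self.age_min < 1 or self.age_max < self.age_min:
            raise ValueError("parameter age_min/age_max define an empty range")
        if self.recruit_year_max < self.recruit_year_min:
            raise ValueError("parameter recruit_year_min/max define an empty range")
        if self.duration_max < 1:
            raise ValueError("parameter duration_max must be >= 1")
        if self.type1_dx_age_max < self.type1_dx_age_min:
            raise ValueError("parameter type1_dx_age_min/max define an empty range")


def _choice(rng: np.random.Generator, options: tuple[str, ...]) -> str:
    return options[int(rng.integers(0, len(options)))]


def _random_date(rng: np.random.Generator, year: int, first_month: int = 1) -> dt.date:
    month = int(rng.integers(first_month, 13))
    day = int(rng.integers(1, 29))
    return dt.date(year, month, day)


def generate(params: GeneratorParams) -> tuple[CohortBundle, pd.DataFrame]:
    """Draw a full synthetic cohort plus its ground-truth table.

    Reproducible given (params, seed); emitted records satisfy all record
    invariants.  The truth table has one row per participant with
    ``true_diabetes`` and ``true_type`` ('type1' / 'type2' / 'none').
    """
    params.validate()
    p = params
    children = np.random.SeedSequence(p.seed).spawn(p.n)
    questionnaires: list[QuestionnaireRecord] = []
    admissions: list[AdmissionRecord] = []
    mbs_claims: list[MbsClaim] = []
    pbs_claims: list[PbsClaim] = []
    linkage: list[LinkageStatus] = []
    truth_status: list[bool] = []
    truth_type: list[str] = []
    ids: list[str] = []

    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"P{i:07d}"
        ids.append(pid)

        female = rng.random() < p.female_fraction
        age = int(rng.integers(p.age_min, p.age_max + 1))
        recruit_year = int(rng.integers(p.recruit_year_min, p.recruit_year_max + 1))
        recruitment_date = _random_date(rng, recruit_year)
        year_of_birth = recruit_year - age

        diabetic = rng.random() < p.prevalence
        type1 = diabetic and rng.random() < p.type1_fraction
        truth_status.append(diabetic)
        truth_type.append("type1" if type1 else ("type2" if diabetic else "none"))

        # true age at diagnosis (defined for diabetics; fabricated for
        # spurious tick-box reports below)
        if type1:
            age_dx_true = int(rng.integers(p.type1_dx_age_min, p.type1_dx_age_max + 1))
        elif diabetic:
            age_dx_true = age - int(rng.integers(1, p.duration_max + 1))
        else:
            age_dx_true = None

        # --- questionnaire ---------------------------------------------
        if diabetic:
            ticked = rng.random() < p.tick_sens
        else:
            ticked = rng.random() < (1.0 - p.tick_spec)
        age_at_diagnosis = None
        if ticked and rng.random() >= p.age_dx_missing_rate:
            if age_dx_true is not None:
                age_at_diagnosis = age_dx_true
            else:
                age_at_diagnosis = age - int(rng.integers(1, p.duration_max + 1))

        other_illness_text = ""
        if diabetic and not ticked and rng.random() < p.free_text_rate:
            pool = _POSITIVE_TEXTS_T1 if type1 else _POSITIVE_TEXTS_T2
            other_illness_text = _choice(rng, pool)
        elif not diabetic and not ticked and rng.random() < p.uncertain_text_rate:
            other_illness_text = _choice(rng, _UNCERTAIN_TEXTS)
        elif rng.random() < p.decoy_text_rate:
            other_illness_text = _choice(rng, _DECOY_TEXTS)

        if diabetic:
            insulin_rate = p.insulin_given_type1 if type1 else p.insulin_given_type2
            reports_insulin = rng.random() < insulin_rate
            reports_oha = rng.random() < p.oha_given_diabetes
        else:
            reports_insulin = reports_oha = False
        metformin_tickbox = reports_oha and rng.random() < p.oha_via_tickbox
        med_parts: list[str] = []
        if reports_insulin:
            med_parts.append(_choice(rng, _INSULIN_BRANDS))
        if reports_oha and not metformin_tickbox:
            med_parts.append(_choice(rng, _OHA_BRANDS))
        if rng.random() < p.decoy_med_rate:
            med_parts.append(_choice(rng, _DECOY_MEDS))
        medication_text = ", ".join(med_parts)

        dva_card = rng.random() < p.dva_prob
        age_at_last_delivery = None
        if female and rng.random() < p.parous_prob:
            age_at_last_delivery = int(rng.integers(18, 46))

        questionnaires.append(
            QuestionnaireRecord(
                participant_id=pid,
                recruitment_date=recruitment_date,
                sex="female" if female else "male",
                year_of_birth=year_of_birth,
                diabetes_tickbox=ticked,
                age_at_diagnosis=age_at_diagnosis,
                other_illness_text=other_illness_text,
                metformin_tickbox=metformin_tickbox,
                medication_text=medication_text,
                dva_card=dva_card,
                age_at_last_delivery=age_at_last_delivery,
            )
        )

        # --- hospital admissions ---------------------------------------
        if rng.random() < p.admit_prob:
            n_adm = 1 + int(rng.poisson(p.extra_admissions))
            adm_codes: list[list[str]] = []
            adm_dates: list[dt.date] = []
            for _ in range(n_adm):
                year = int(rng.integers(p.admission_year_min, p.admission_year_max + 1))
                first_month = 7 if year == 2000 else 1
                adm_dates.append(_random_date(rng, year, first_month))
                n_codes = 1 + int(rng.integers(0, 3))
                idx = rng.choice(len(_BACKGROUND_CODES), size=n_codes, replace=False)
                adm_codes.append([_BACKGROUND_CODES[j] for j in idx])
            if diabetic:
                code_recorded = rng.random() < p.code_sens
                diabetes_code = "E10.9" if type1 else "E11.9"
            else:
                code_recorded = rng.random() < (1.0 - p.code_spec)
                diabetes_code = "E14.9"
            if code_recorded:
                target = int(rng.integers(0, n_adm))
                pos = int(rng.integers(0, len(adm_codes[target]) + 1))
                adm_codes[target].insert(pos, diabetes_code)
            if female and p.gdm_code_prob > 0 and rng.random() < p.gdm_code_prob:
                target = int(rng.integers(0, n_adm))
                adm_codes[target].append("O24.4")
            for codes, date in zip(adm_codes, adm_dates):
                admissions.append(AdmissionRecord(pid, date, tuple(codes)))

        # --- HbA1c service claims --------------------------------------
        n_mbs_years = p.mbs_year_max - p.mbs_year_min + 1
        rate = p.hba1c_rate_diabetes if diabetic else p.hba1c_rate_other
        n_claims = int(rng.poisson(n_mbs_years * rate))
        for _ in range(n_claims):
            year = int(rng.integers(p.mbs_year_min, p.mbs_year_max + 1))
            mbs_claims.append(MbsClaim(pid, _random_date(rng, year), 66551))

        # --- pharmacy dispensings --------------------------------------
        p_med = p.pbs_claim_sens if diabetic else p.pbs_claim_fpr
        if rng.random() < p_med:
            cls = (
                "insulin"
                if diabetic and rng.random() < p.pbs_insulin_fraction
                else "biguanide"
            )
            days = int(rng.integers(1, 366))
            pbs_claims.append(
                PbsClaim(pid, recruitment_date - dt.timedelta(days=days), cls)
            )
        if rng.random() < p.background_claim_prob:
            for _ in range(1 + int(rng.poisson(0.5))):
                days = int(rng.integers(1, 366))
                pbs_claims.append(
                    PbsClaim(
                        pid, recruitment_date - dt.timedelta(days=days), "non_diabetes"
                    )
                )
        if rng.random() < p.old_claim_prob:
            days = int(rng.integers(400, 701))
            pbs_claims.append(
                PbsClaim(pid, recruitment_date - dt.timedelta(days=days), "non_diabetes")
            )

        linkage.append(
            LinkageStatus(
                participant_id=pid,
                linked_apdc=rng.random() < p.link_prob,
                linked_medicare=rng.random() < p.link_prob,
            )
        )

    bundle = CohortBundle(questionnaires, admissions, mbs_claims, pbs_claims, linkage)
    truth = pd.DataFrame(
        {"participant_id": ids, "true_diabetes": truth_status, "true_type": truth_type}
    )
    return bundle, truth


def default_window_config(params: GeneratorParams) -> WindowConfig:
    """Criterion windows consistent with the generator's date model."""
    return WindowConfig(
        apdc_start=dt.date(params.admission_year_min, 7, 1),
        apdc_end=dt.date(params.admission_year_max, 12, 31),
        hba1c_year_start=params.mbs_year_min + 1,
        hba1c_year_end=params.mbs_year_max,
    )


# ---------------------------------------------------------------------------
# closed-form oracle
# ---------------------------------------------------------------------------


def _questionnaire_probs(p: GeneratorParams) -> dict[str, dict[str, float]]:
    """Per true-status stratum: weight and self-report route probabilities.

    ``dia_tick`` is the tick-box route into the diabetes group (it alone is
    subject to the diagnosis-year exclusion, because only tick-box
    responders are asked their age at diagnosis); ``dia_other`` covers the
    free-text and insulin-text routes.
    """
    out: dict[str, dict[str, float]] = {}
    for stratum, weight, ins in (
        ("type1", p.prevalence * p.type1_fraction, p.insulin_given_type1),
        ("type2", p.prevalence * (1.0 - p.type1_fraction), p.insulin_given_type2),
    ):
        ts, ftr, oha = p.tick_sens, p.free_text_rate, p.oha_given_diabetes
        out[stratum] = {
            "weight": weight,
            "dia_tick": ts,
            "dia_other": (1 - ts) * (ftr + (1 - ftr) * ins),
            "uncertain": (1 - ts) * (1 - ftr) * (1 - ins) * oha,
            "non": (1 - ts) * (1 - ftr) * (1 - ins) * (1 - oha),
        }
    out["nd"] = {
        "weight": 1.0 - p.prevalence,
        "dia_tick": 1.0 - p.tick_spec,
        "dia_other": 0.0,
        "uncertain": p.tick_spec * p.uncertain_text_rate,
        "non": p.tick_spec * (1.0 - p.uncertain_text_rate),
    }
    return out


def _duration_distribution(p: GeneratorParams, stratum: str) -> tuple[np.ndarray, np.ndarray]:
    """(values, weights) of years-since-diagnosis for tick-box responders."""
    if stratum == "type1":
        ages = np.arange(p.age_min, p.age_max + 1)
        dx_ages = np.arange(p.type1_dx_age_min, p.type1_dx_age_max + 1)
        durations = (ages[:, None] - dx_ages[None, :]).ravel()
        weights = np.full(durations.size, 1.0 / durations.size)
    else:  # type2 diabetics and spurious non-diabetic reports
        durations = np.arange(1, p.duration_max + 1)
        weights = np.full(durations.size, 1.0 / durations.size)
    return durations, weights


def _dx_year_distribution(p: GeneratorParams, stratum: str) -> tuple[np.ndarray, np.ndarray]:
    durations, dur_w = _duration_distribution(p, stratum)
    years = np.arange(p.recruit_year_min, p.recruit_year_max + 1)
    dx_years = (years[:, None] - durations[None, :]).ravel()
    weights = (np.full(years.size, 1.0 / years.size)[:, None] * dur_w[None, :]).ravel()
    return dx_years, weights


def _apdc_dx_exclusion_prob(p: GeneratorParams, stratum: str) -> float:
    """P(diagnosis year > last admission year | admitted, age reported).

    The last admission year is the max of M iid uniform years on
    [admission_year_min, admission_year_max], M = 1 + Poisson(extra).
    E[F^M] = F * exp(-extra * (1 - F)) with F the single-year CDF.
    """
    dx_years, weights = _dx_year_distribution(p, stratum)
    n_years = p.admission_year_max - p.admission_year_min + 1
    f = np.clip((dx_years - p.admission_year_min) / n_years, 0.0, 1.0)
    return float(np.sum(weights * f * np.exp(-p.extra_admissions * (1.0 - f))))


def _mbs_dx_exclusion_prob(p: GeneratorParams, stratum: str, window_end: int) -> float:
    dx_years, weights = _dx_year_distribution(p, stratum)
    return float(np.sum(weights[dx_years > window_end]))


def _stats_from_float_cells(a: float, b: float, c: float, d: float) -> AgreementStats:
    n = a + b + c + d
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    return AgreementStats(
        sensitivity=a / (a + c),
        specificity=d / (b + d),
        ppv=a / (a + b),
        npv=d / (c + d),
        observed_agreement=p_o,
        expected_agreement=p_e,
        kappa=(p_o - p_e) / (1.0 - p_e),
    )


def expected_cells(
    params: GeneratorParams, source: str, config: WindowConfig | None = None
) -> dict[str, float]:
    """Expected 2x2 cell probabilities (conditional on analysis inclusion
    and a non-uncertain status) under the generator's probability model.

    Keys: ``tp``, ``fp``, ``fn``, ``tn`` (normalised to sum to 1).
    """
    params.validate()
    p = params
    if source not in ("apdc", "mbs", "pbs"):
        raise ValueError(f"unknown source {source!r}")
    if source == "apdc" and p.gdm_code_prob > 0:
        raise ValueError(
            "closed-form APDC expectations are not available when gestational "
            "codes are generated (gdm_code_prob > 0)"
        )
    config = config or default_window_config(p)
    q = _questionnaire_probs(p)
    miss = p.age_dx_missing_rate

    cells = {"tp": 0.0, "fp": 0.0, "fn": 0.0, "tn": 0.0}
    for stratum, probs in q.items():
        diabetic = stratum != "nd"
        if source == "apdc":
            pos = p.code_sens if diabetic else 1.0 - p.code_spec
            excl = _apdc_dx_exclusion_prob(p, stratum)
            keep_tick = miss + (1.0 - miss) * (1.0 - excl)
            w_dia = probs["weight"] * (probs["dia_tick"] * keep_tick + probs["dia_other"])
            w_non = probs["weight"] * probs["non"]
            joint = {"pos": pos, "neg": 1.0 - pos}
        elif source == "mbs":
            rate = p.hba1c_rate_diabetes if diabetic else p.hba1c_rate_other
            n_years = config.hba1c_year_end - config.hba1c_year_start + 1
            pos = float(sps.poisson.sf(config.hba1c_min_claims - 1, n_years * rate))
            excl = _mbs_dx_exclusion_prob(p, stratum, config.hba1c_year_end)
            keep_tick = miss + (1.0 - miss) * (1.0 - excl)
            w_dia = probs["weight"] * (probs["dia_tick"] * keep_tick + probs["dia_other"])
            w_non = probs["weight"] * probs["non"]
            joint = {"pos": pos, "neg": 1.0 - pos}
        else:  # pbs: inclusion requires at least one dispensing in lookback
            p_med = p.pbs_claim_sens if diabetic else p.pbs_claim_fpr
            w_dia = probs["weight"] * (probs["dia_tick"] + probs["dia_other"])
            w_non = probs["weight"] * probs["non"]
            joint = {"pos": p_med, "neg": (1.0 - p_med) * p.background_claim_prob}
        cells["tp"] += w_dia * joint["pos"]
        cells["fp"] += w_dia * joint["neg"]
        cells["fn"] += w_non * joint["pos"]
        cells["tn"] += w_non * joint["neg"]
    total = sum(cells.values())
    return {k: v / total for k, v in cells.items()}


def expected_stats(
    params: GeneratorParams, source: str, config: WindowConfig | None = None
) -> AgreementStats:
    """Analytically expected agreement statistics of self-report vs the
    chosen criterion standard under the generator's probability model."""
    c = expected_cells(params, source, config)
    return _stats_from_float_cells(c["tp"], c["fp"], c["fn"], c["tn"])
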