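# Methods

## Phenotyping algorithm

Each participant is assigned exactly one of three statuses from the baseline
questionnaire, by a fixed-order decision list:

1. diabetes tick box ticked → **diabetes** (evidence `tickbox`);
2. otherwise the free-text "other important illness" box is matched against
   two phrase lists: uncertainty phrases (pre-diabetes, borderline diabetes,
   diabetes insipidus, impaired glucose tolerance) → **uncertain**; else
   diabetes-specific phrases (diabetes, sugar diabetes, type 1/2 diabetes,
   grade 2 diabetes, controlled diabetes, …) → **diabetes** (`free_text`).
   Uncertainty phrases are checked first, so "diabetes insipidus" is routed
   to uncertain even though it contains "diabetes";
3. otherwise the medication fields: an insulin product in the free-text
   medication box → **diabetes** (`insulin_text`); an oral hypoglycaemic
   agent only (including the dedicated Diabex/Diaformin/Metformin tick box)
   → **uncertain** (`oha_text`);
4. otherwise **non-diabetes**.

Matching is case-insensitive, whitespace-normalised, whole-phrase with word
boundaries; hyphens and other punctuation count as boundaries, so
"diabetes" does not match inside "diabetic" but does match inside
"pre-diabetes" (intercepted by rule 2's precedence). There is no fuzzy
matching or spelling correction: a misspelling is handled by adding a
variant to the lexicon CSV, which — not the code — is the source of truth
for both the medication products (insulin, biguanide, sulphonylurea,
thiazolidinedione, alpha-glucosidase inhibitor, DPP-4 inhibitor, premixed,
exenatide, meglitinide classes) and the diagnosis phrases. Self-reported
insulin/OHA use is recorded for every participant regardless of the rule
that fixed their status, because typing and the dispensing comparison need
it for all groups. Incident (post-recruitment) diabetes is deliberately out
of scope.

## Type classification

Applied only to the diabetes group, in order: declared type in free text
(type 1 before type 2 when both appear); insulin use with age at diagnosis
≤ 30 ("before age 31", read strictly) or missing → type 1; women diagnosed
strictly before the age at their last delivery and on no current diabetes
medication → gestational/other (ties at equal ages are *not* gestational —
the questionnaire records ages, not dates, so a tie is uninformative);
residual → type 2. A declared type outranks the insulin/age rule; conflicts
(declared type 2 but insulin since youth) are counted and logged rather than
silently resolved. Gestational and "other" are merged into one label, as the
questionnaire cannot separate them.

## Criterion standards

* **Hospital (APDC)**: diabetes = any of E10/E11/E13/E14/O24.0–O24.3 as a
  code *prefix* (dots retained, so "E11" covers "E11.9") in any diagnostic
  position of any admission in the closed window 2000-07-01..2009-12-31.
  Exclusions, in precedence order: not linked; no admission in window;
  self-reported diagnosis year (year of birth + age at diagnosis, year
  resolution) after the last admission year; only gestational (O24-prefix)
  diabetes codes. Hospital-coded type uses the precedence E10 > E11 >
  (E13, O24.0–O24.3) > E14 > none; the collections record one type per
  participant, and the precedence favours the more specific code when
  several families co-occur.
* **HbA1c claims (MBS)**: at least `hba1c_min_claims` (default 1) claims
  for item 66551 with service year in 2005–2009. Claims were extracted from
  2004 but counted from 2005, matching the analysed five-year window.
  Exclusions: not linked to Medicare; diagnosis year after the window end.
* **Dispensings (PBS)**: at least one insulin or OHA dispensing in
  [recruitment − 365 d, recruitment). The right end is open — a dispensing
  on the recruitment day is not "prior to recruitment"; all other windows
  are closed intervals. Exclusions: not linked; no dispensing of any kind in
  the lookback (no capture opportunity); DVA card holders (their
  dispensings bypass this collection).

For every source, included + excluded = cohort size, the exclusion reasons
are mutually exclusive by the stated precedence, and shrinking any window
can only destroy, never create, criterion positives (property-tested).

## Agreement statistics

From a 2×2 table (rows self-report, columns criterion) the package computes
sensitivity, specificity, PPV, NPV, observed agreement p_o, chance
agreement p_e from the marginals, and kappa = (p_o − p_e)/(1 − p_e) — the
two-rater Fleiss formula, identical to Cohen's kappa for two raters; no
continuity correction. Zero-denominator statistics are reported as `nan`
(undefined), never 0. Uncertain-status participants never enter the 2×2;
they are tabulated in a separate (positive, negative) row. Percentages are
reported to one decimal and kappa to two in the text report; raw
proportions are kept in the machine-readable CSV. Tests cross-check kappa
against `sklearn.metrics.cohen_kappa_score` and a brute-force label
expansion on random tables, and verify transpose invariance, kappa = 1 iff
off-diagonals vanish, and kappa = 0 on product (independent-margin) tables.

## Synthetic cohort generator

The generator emulates the confusion structure of a linked validation
study: per participant it draws a true status (prevalence 0.09 by default)
and type (type-1 fraction 0.037), then conditionally independent recorded
signals. Questionnaire: tick-box sensitivity 0.94 / specificity 0.999;
free-text rate 0.08 among unticked diabetics; uncertainty-text rate 0.0006
among non-diabetics; insulin self-report 0.95 (type 1) / 0.07 (type 2); OHA
self-report 0.58; age at diagnosis missing for 5% of tick-box responders.
Hospital: admission probability 0.72, admission count 1 + Poisson(1.5),
years uniform on 2000–2009; a diabetes code (E10.9/E11.9 by true type) is
recorded with probability 0.84 for diabetics, a spurious E14.9 with
probability 0.02 for non-diabetics, placed at a random position among 1–3
background codes. Claims: HbA1c counts Poisson(years × rate) with annual
rates 0.38 (diabetic) / 0.01 (other) over the 2004–2009 extraction window;
a diabetes dispensing with probability 0.714 / 0.0035 in the 12-month
lookback plus background non-diabetes dispensings (probability 0.88); DVA
card 0.024; linkage 0.997 per collection. Defaults were set once from the
margins the study design implies (observed prevalence, admission fraction,
coded-diabetes fraction among admitted diabetics, dispensing fraction, DVA
fraction); rates the design does not pin down (background dispensings,
decoy text, date model) use round realistic values.

Dates are discrete and enumerable: recruitment year uniform 2006–2009, age
uniform 45–84, diagnosis 1–20 years before recruitment for type 2 (and for
spurious reports), age 5–30 for type 1. That makes the expected agreement
statistics available in closed form: `expected_stats` propagates the
questionnaire route probabilities, the per-source positive probabilities,
and the exclusion couplings through the law of total probability. The
"diagnosed since last admission" exclusion is handled exactly by
enumerating the diagnosis-year distribution against
P(last admission year < y) = F(y)·exp(−λ(1−F(y))) for the 1 + Poisson(λ)
admission count. The closed form raises rather than approximates when
gestational codes are enabled (`gdm_code_prob > 0`), since that exclusion
couples to the code draw.

Reproducibility: a single seed; per-participant substreams via
`SeedSequence.spawn`, so enlarging a cohort never perturbs earlier
participants and identical (params, seed) give byte-identical output files.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real free text (misspellings, abbreviations,
narrative), correlation between self-reported medications and dispensing
claims beyond true status, demographic structure and differential response,
seasonality or clustering of admissions and claims, under-capture from
pathology-claim "coning" or sub-co-payment dispensings, and the published
cohort-specific exclusion counts. Agreement between the pipeline and the
closed form validates the implementation logic, not the questionnaire's
real-world accuracy.

## Numerical and design choices

* Problem sizes: property tests use 200–2,000-participant cohorts; the
  end-to-end oracle comparison uses 100,000 participants, where binomial
  standard errors on sensitivity are ~0.5%, small enough to detect logic
  errors while keeping the suite fast.
* Monte-Carlo vs closed-form tolerance is three binomial standard errors on
  each statistic's own denominator.
* The free-text-uncertain and OHA-only uncertain groups are disjoint by
  construction (free text is evaluated first); the pipeline reports both
  counts and their union separately, since their overlap in the original
  study is not derivable from the published margins.
* CSV dialect: comma-separated, UTF-8, mandatory header, ISO-8601 dates,
  empty string for missing; admission code lists semicolon-joined so one
  admission is one row. Readers are strict: schema or invariant violations
  are fatal with 1-based row numbers; duplicate participant ids are fatal.
* Statistics on degenerate tables: an all-zero table raises; a zero
  marginal yields `nan` for the statistics it defines.

## Known limitations

* Phenotyping is lexicon-bound; recall on real free text depends entirely
  on lexicon coverage.
* The type algorithm is known to agree poorly with hospital-coded type even
  in the original setting (≈ 42% row agreement for type 1); it is provided
  for cohort description, not clinical adjudication.
* Probabilistic person-level linkage is out of scope; linkage is consumed
  as boolean flags.
* No confidence intervals on the agreement statistics; the intended use is
  large cohorts where sampling error is dominated by design effects.
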