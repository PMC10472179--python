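# Methods

This note records the scientific and numerical choices behind `diisurv`:
the scoring model, the cohort-derivation conventions, the survival stage,
and what the synthetic-data generator does and does not emulate.

## The dietary inflammatory index

The score for one subject is `DII = Σ_i w_i · (2·Φ(z_i) − 1)` with
`z_i = (X_i − μ_i)/σ_i`, where `X_i` is the mean daily intake of food
parameter *i* (from a multi-day 24-hour recall), `μ_i`/`σ_i` are global
reference statistics, and `w_i ∈ [−1, 1]` is the literature-derived
inflammatory effect weight. Conventions:

* **Percentile transform.** The "percentile" step uses the standard normal
  CDF of the z-score, not an empirical within-sample percentile. This is an
  assumption: it makes scores deterministic per subject and comparable
  across cohorts, at the cost of leaning on the reference SD for the shape
  of the intake distribution. It is the convention of established DII
  implementations and is applied uniformly here.
* **Missing parameters.** Studies rarely measure all 45 canonical
  parameters (surveys against a national food-composition table typically
  reach 28). Absent parameters contribute nothing and are reported in
  `skipped_parameters`; the total is not rescaled. A `min_coverage`
  argument turns low coverage into an error for users who want that guard.
* **Energy adjustment (density method).** Intakes are converted to amounts
  per 1000 kcal and scored against a per-1000 kcal reference database. The
  energy parameter is excluded there — its density is identically
  1000 kcal — and the exclusion is logged. The adjusted score is invariant
  under proportional scaling of all intakes and energy (tested as a
  property).
* **Zero intakes** score as-is (`z = −μ/σ`); no log transform is applied,
  since the centred percentile already bounds each parameter's influence.
* **Reference values.** Published global means/SDs/effect weights are not
  redistributed with this package; reference tables are user-supplied
  delimited text (`name, global_mean, global_sd, effect_score`, dialect
  declared by the caller). Tests and examples use synthetic reference
  tables, so no literature values are load-bearing in CI.

## Intake processing

Food-mode records (grams per subject-day) are joined against a composition
table holding nutrients per 100 g; per-day totals are
`Σ amount/100 × per-100 g`, linear in amounts. Days are averaged
unweighted by default — the typical 2-weekday + 1-weekend recall design
states no weights — with an optional weights vector (e.g. 5/7–2/7).
Subjects with fewer days than expected are averaged over available days and
logged (strict mode errors). Household-inventory apportionment of oils and
condiments is out of scope; inputs are assumed individualised.

## Cohort derivation

* **BMI** = weight/(height in m)²; classes at 18.5/24.0/28.0 kg/m²
  (left-inclusive, so 24.00 is in the 24.0–27.9 class).
* **MAMC** = mid-upper-arm circumference (cm) − π·(triceps skinfold in
  mm)/10. TSF is taken in millimetres at the schema level; a non-positive
  result is flagged implausible rather than erroring.
* **WHR/abdominal obesity**: WHO Asian cutoffs, boundary inclusive
  (≥ 0.90 men, ≥ 0.85 women).
* **OSTA** = 0.2·(weight − age); classes low (> −1), medium, high (< −4).
  The printed class definitions leave −1 and −4 unassigned; the package
  assigns both boundaries to the medium class (closed interval [−4, −1]),
  with an `outer` policy available.
* **Exclusion cascade**, in order: age < 18; pregnant/nursing/disabled;
  missing outcome or follow-up data (including zero follow-up); missing or
  implausible energy (strictly < 700 or > 5000 kcal/d, so the boundary
  values are retained); baseline fracture; prior MI/stroke/tumour; body
  measurement outliers. No plausibility rule is published for the last
  step; the defaults (height 100–220 cm, weight 25–200 kg, WHR 0.5–1.5)
  are configurable and every exclusion is logged with the subject's first
  failing rule, so counts reconcile exactly and the cascade is idempotent.
* **Quintiles** are assigned within sex by rank: the sorted scores are cut
  into five contiguous blocks whose sizes differ by at most one, and tied
  values all take the block of their first sorted occurrence. This
  tie-handling keeps labels monotone in the score and is mirrored by the
  brute-force oracle in the test suite.
* **Person-time.** Follow-up runs from the baseline survey to the first of:
  reconstructed fracture date, last attended survey, final administrative
  wave — in years of 365.25 days. Fracture timing is recalled as an integer
  age; the event date is reconstructed as `baseline + (fracture_age −
  floor(age) + 0.5)` years, treating the baseline as birthday-aligned
  (mid-year convention, configurable offset). A recalled age below the
  baseline age is a prevalent case and errors. When the reconstructed date
  lands after the censor date — possible within half a survey interval —
  the event is kept and person-time capped at the censor date.

## Survival stage

Cox partial likelihoods are maximised by lifelines with the Efron tie
approximation (ties are common here because reconstructed event times sit
on a half-year grid). Adjustment sets are nested: level 1 demographics
(age, sex, residence, education, income, marital status); level 2 adds
smoking, drinking, physical activity, BMI, MAMC, WHR; level 3 adds
hypertension, diabetes and the OSTA class. Categoricals enter as
first-level-dropped indicators; constant columns are dropped silently
(e.g. sex inside a sex-stratified fit).

* **Quintile models** use indicator contrasts against Q1; the reference row
  is emitted with HR exactly 1 and no CI. CI bounds are
  `exp(β ± 1.96·se)` with the conventional 1.96.
* **Trend tests** refit with a single ordered exposure: the within-sex
  median DII of each quintile by default (integer 1–5 coding available).
  The p-value is the Wald p of that coefficient; a constant exposure yields
  a missing result with a warning.
* **Restricted cubic splines** use the Harrell truncated-power natural
  basis (linear beyond boundary knots), default 4 knots at the
  5th/35th/65th/95th exposure percentiles. The curve is re-centred so
  HR = 1 exactly at the cohort median; the pointwise band comes from the
  delta method on the spline-coefficient covariance. The overall test is
  the joint Wald test of all spline terms; nonlinearity is the Wald test of
  the nonlinear terms only. Both are reported; Wald was chosen over the
  LRT for uniformity with the other tests, and its null calibration is
  verified by simulation in the acceptance suite.
* **Subgroups** use binary stratifiers (age ≥ 50, BMI ≥ 24,
  smoker/drinker status, abdominal obesity, OSTA ≤ −1, MAMC above/below
  the within-sex median by default with a fixed-value override). The
  interaction p comes from a pooled model adding quintile × stratifier
  products, tested jointly (4 df Wald). Strata without events are reported
  unavailable rather than failing the whole analysis.
* **Sensitivity analyses** rerun the fully adjusted quintile and continuous
  fits on four disease-exclusion subsets: no hypertension; no diabetes;
  neither; not-both. Quintile labels from the full sex-specific cohort are
  retained so the exposure definition is constant across subsets.
* **Component analyses** quintile one nutrient's energy-adjusted
  contribution score within sex and rerun the adjusted fit; twelve
  nutrients (macronutrients plus common micronutrients) are supported.
* **Proportional-hazards diagnostics** report (a) a likelihood-ratio test
  of exposure × log(t) interactions, fitted on risk-set-split long-format
  data with a time-varying Cox model (both the full and reduced models are
  fitted on the same split data so the tie handling cancels), and (b)
  scaled-Schoenfeld residual tests per covariate. The LRT gives the global
  verdict at α; the per-covariate tests are corroboration only, because
  testing each of many covariates at raw α would flag well-specified
  models far more often than α.

## Synthetic cohorts

The generator emulates the *structure* of a 1997–2015 periodic nutrition
survey, with defaults fixed once as study conditions:

* n = 6000 subjects, 54% women; survey waves 1997, 2000, 2004, 2006, 2009,
  2011, 2015 (every 2–4 years), baseline at the first wave.
* Intakes per sex are log-normal with a Gaussian copula (exchangeable
  ρ = 0.3), so marginal shape and correlation are set independently; men's
  intakes are scaled up by ~17% relative to women's. Daily energy is
  composed from macronutrients at 4/4/9 kcal/g (7 for alcohol) plus
  log-normal non-macronutrient energy, which makes the density method's
  energy identity meaningful. Reference means/SDs match the intake
  distributions, so z-scores are centred by construction.
* Anthropometrics come from truncated normals chosen to put BMI near
  23, men's WHR near the 0.90 cutoff and women's near 0.84, and MAMC near
  22/20 cm; categorical covariates (residence, education, income, activity,
  smoking 62%/3.8% by sex, drinking, hypertension 7%, diabetes 1.7%) use
  fixed prevalences in the range typical of such cohorts.
* Outcomes follow a Weibull proportional-hazards law (shape 1.2) with
  linear predictor `0.12·(DII − mean) + 0.03·(age − mean) − 0.10·woman +
  0.10·smoker` by default. The scale is calibrated by bisection against a
  closed-form (quadrature) expression for the expected event fraction under
  administrative censoring at 18 years and independent exponential dropout
  (0.04/y), targeting 7.5% events — the event-rate regime of a cohort with
  ~900 fractures among ~12,000 adults with 9-year median follow-up.
* **Observation model.** True event times are degraded exactly the way a
  questionnaire degrades them: the event is observed only if the subject
  attends a wave after it, and then only as the integer age at the event.
  This is what makes the cohort stage's date-reconstruction logic testable:
  reconstructed person-time sits within half a year of the truth for
  observed events, and events whose subjects drop out before the next wave
  are (correctly, non-informatively) censored at the last attended wave.

What the generator does **not** emulate: household sampling design and
survey weights, geographic clustering, wave-specific attendance patterns
beyond independent dropout, diet–covariate confounding (intakes are drawn
independently of the covariates), food-item-level menus, and recall
measurement error in the intakes themselves. Passing tests therefore
demonstrate that the pipeline recovers known effects under clean
conditions — estimator correctness, test calibration, power — not that any
particular real-world association holds.

## Verification scale and numerics

Simulation-based checks use fixed seeds throughout. The estimator
recovery/coverage check runs 100 replicates at n = 6000 (bias ≈ 0.001 on a
true log-HR of 0.12; 95% CI coverage 0.98); null calibration of the trend,
interaction and nonlinearity tests runs 500 replicates at n = 1500; the
interaction power check runs 20 replicates at n = 6000 with ±0.2 log-HR by
residence. Replicate counts were chosen so each band is statistically
meaningful at the stated problem size. Scoring agrees with a loop-based
oracle to 1e−10; conservation of the total against its components holds to
1e−12; CI bounds reproduce `exp(β ± 1.96·se)` to 1e−9. Weibull scale
calibration bisects to a relative tolerance of 1e−4 on a 200-point
quadrature grid.

## Known limitations

* The normal-CDF percentile convention is an assumption where the source
  methodology is ambiguous; an empirical-percentile variant would give
  different absolute scores (rank-based analyses downstream are less
  affected).
* Recalled fracture ages are taken at face value; recall error beyond
  integer truncation is not modelled, and only first fractures are used.
* Complete-case handling throughout (the exclusion cascade); no imputation.
* No competing risks or recurrent events; no multiple-testing correction
  across subgroups, matching common reporting practice in this literature.
* The spline's published curves in any particular study are not exactly
  reconstructible without knowing knot count and placement; defaults here
  are the standard epidemiological choice and are configurable.
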