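# diisurv

Dietary inflammatory index (DII) scoring and sex-stratified fracture
survival analysis for longitudinal nutrition cohorts.

Chronic low-grade inflammation is a suspected driver of osteoporosis and
fragility fractures, and diet is a major modifiable source of inflammation.
The DII condenses a diet into one number — the literature-weighted sum of
standardised, percentile-centred food-parameter intakes — with positive
scores marking pro-inflammatory diets. `diisurv` implements the full
analysis pipeline used to relate that score to fracture hazard in a
periodic-survey cohort: scoring, covariate derivation, exclusion rules,
person-time construction from questionnaire-recalled fracture ages, and the
Cox proportional-hazards analysis stage. Because national survey data of
this kind are access-restricted, the package ships a synthetic cohort
generator with known ground truth, so every stage is testable end to end.

It is aimed at nutritional epidemiologists and biostatisticians who work
from Python: the importable API is the interface, and `examples/` holds one
short narrative script per capability.

## The score and the models

For food parameter *i* with intake `X_i`, global reference mean `μ_i`, SD
`σ_i` and inflammatory effect weight `w_i` (|w| ≤ 1, negative =
anti-inflammatory):

    DII = Σ_i  w_i · ( 2·Φ( (X_i − μ_i) / σ_i ) − 1 )

where Φ is the standard normal CDF. The centred percentile bounds every
parameter's influence to (−1, 1). The energy-adjusted variant scores
nutrient densities `X_i / (E/1000 kcal)` against a per-1000 kcal reference
database (the density method); the energy parameter itself is dropped there
because its density is constant.

The survival stage fits Cox proportional-hazards models (Efron ties, via
lifelines) with three nested adjustment levels — demographics; + lifestyle
and physical measures (BMI, midarm muscle circumference, waist-hip ratio);
+ disease history and the OSTA osteoporosis-risk class — with the DII
entered as sex-specific quintiles (Q1 reference), as a continuous term, or
as a restricted cubic spline centred at the sex-specific median
(HR(median) = 1). Quintile trend tests, subgroup analyses with
multiplicative interaction terms, disease-exclusion sensitivity analyses,
per-nutrient component analyses and proportional-hazards diagnostics mirror
the standard reporting layout of cohort studies in this area.

## Worked example

`examples/fit_models.py` simulates a cohort whose true continuous-DII log
hazard ratio is 0.12 per unit, then fits the nested models on women:

```
women: n=1740, events=136
model 1: 1 (ref) | 1.18 (0.62-2.26) | 1.85 (1.01-3.38) | 1.99 (1.10-3.61) | 2.00 (1.09-3.64)   trend p=0.005
model 2: 1 (ref) | 1.21 (0.63-2.31) | 1.86 (1.02-3.42) | 1.96 (1.08-3.56) | 1.99 (1.09-3.64)   trend p=0.006
model 3: 1 (ref) | 1.25 (0.65-2.38) | 1.93 (1.05-3.55) | 2.01 (1.10-3.67) | 2.05 (1.12-3.76)   trend p=0.005
```

Each cell is the hazard ratio (95% CI) for a DII quintile against the least
inflammatory quintile Q1; the rising pattern with a small trend p says
fracture hazard increases monotonically with dietary inflammatory
potential, and its stability across adjustment levels says the association
is not explained by the measured confounders. `examples/score_dii.py` shows
the scoring engine itself:

```
high_veg: DII = -1.346
high_fat: DII = +1.396
high_fat energy-adjusted DII = +1.266
```

Other scripts cover recall ingestion (`ingest_recalls.py`), covariate
derivation and exclusions (`derive_cohort.py`), spline dose-response
(`rcs_curve.py`) and the synthetic observation model
(`simulate_cohort.py`). A commented scenario file for the generator is in
`examples/scenario.yaml`.

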