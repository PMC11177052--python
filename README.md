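# icuglucose

24-hour variation in blood glucose during continuous enteral nutrition in
ICU patients: a tested, end-to-end analysis pipeline — EHR-style event
curation, pharmacokinetically corrected exposure-window matching, a nested
random-intercept model sequence with hourly estimated-marginal-means
profiling, a gradient-boosted-tree/TreeSHAP cross-check, and subgroup
profiling — exercised on a synthetic cohort generator with known ground
truth.

## The scientific problem

Glucose measurements in the ICU are repeated within patients, sampled
unevenly around the clock, and entangled with care schedules (nutrition
interruptions, insulin, dextrose, glucocorticoids, routine lab rounds). A
crude hourly mean therefore mixes any endogenous circadian signal with the
daily rhythm of care. This package isolates the clock-time effect: glucose
`y_ij` (mmol/L) of patient *i* at hour-of-day `h(t_ij)` is modelled as

    y_ij = beta_0 + x_ij' beta + gamma_{h(t_ij)} + b_i + e_ij,
    b_i ~ N(0, tau^2),   e_ij ~ N(0, sigma^2),

where `x_ij` holds the patient covariates (age band, sex, diabetes) and the
*time-matched* exposure state (carbohydrate, insulin and dextrose
administration bands, glucocorticoid flag) after pharmacokinetic window
corrections (insulin +0.5 h onset and +2/4/10/12 h class-specific
persistence, glucocorticoids +24 h, dextrose pushes 10 min), and
`gamma_h` (h = 0..23, `gamma_0 = 0`) is the hour-of-day effect. Four nested
models (intercept → +patient → +exposures → +hour) are compared by ML
likelihood-ratio tests; variance components come from REML; the adjusted
24-h profile is the hourly estimated marginal mean over an equal-weight
reference grid, summarised by its first harmonic (cosinor peak time and
peak-to-trough). An XGBoost model with continuous features and TreeSHAP
hour-of-day attributions provides a model-free cross-check, and subgroup
refits (ventilation, mortality, sedation, ICU day, sample type, sampling
frequency, insulin requirement) probe robustness. Details and conventions:
`docs/methods.md`; input formats: `docs/schemas.md`.

Because real credentialed ICU databases cannot ship with the code, the
package includes a first-class synthetic cohort generator whose default
truth mirrors the reference study conditions (intercept 6.6 mmol/L,
diabetes +2.2, variances 2.8/5.4, sinusoidal hour effect peaking at 10:00);
every claim the pipeline makes is tested against that known truth.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 0    # 500-patient cohort
python analysis/02_curate_match.py                # curation + matching
python analysis/03_fit_models.py                  # models, LRTs, EMM profile
```

which prints (seed 0):

```
500 stays -> 425 included
  select_cohort: 500 -> 425
  measurements_in_included_stays: 16868 -> 16868
  validity_filter: 16868 -> 16711
  dedupe_simultaneous: 16711 -> 16360
  restrict_to_enteral_nutrition: 16360 -> 12503
analysis table: 12503 rows -> results/curated/analysis_table.csv

fitted m1..m4 on 12503 rows / 425 patients
  variance components (REML, m4): patient 3.02, residual 5.48
  LRT m1 vs m2: chi2(df=5) = 139.4, p = 2.4e-28
  LRT m2 vs m3: chi2(df=10) = 579.4, p = 4.6e-118
  LRT m3 vs m4: chi2(df=23) = 341.9, p = 1.4e-58
  EMM profile: peak 10.99 mmol/L, cosinor peak 10:00, peak-to-trough 1.08 mmol/L
```

75 of the 500 stays were planted to violate an inclusion criterion and all
75 are excluded, each for its planted reason; the validity, deduplication
and nutrition-restriction steps drop the planted invalid values, duplicate
samples and off-nutrition measurements. The fitted variance components
(3.02 / 5.48) recover the generating values (2.8 / 5.4) within sampling
error, adding the hour term improves fit decisively (χ², df = 23), and the
adjusted profile recovers the injected 10:00 peak and ≈1 mmol/L
peak-to-trough. `analysis/04_gbm_shap.py` reproduces the same rhythm from
the SHAP hour attributions (cosinor peak 10:00), `analysis/05_subgroups.py`
writes per-subgroup profiles, and `analysis/06_confounding.py` shows that on
a cohort with *zero* true time effect but diurnal exposure schedules the
crude profile swings ≈0.7 mmol/L while the adjusted hourly effect stays at
the noise floor (≈0.06).

The same stages are available as a CLI for external data in the documented
CSV schemas: `icuglucose synth | validate | curate | match | fit |
subgroups | report | run`.

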