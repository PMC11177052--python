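# Input table schemas

All tables are comma-separated UTF-8 CSV with a header row (RFC-4180
quoting). Timestamps are timezone-naive ISO-8601 at second resolution,
`YYYY-MM-DDTHH:MM:SS`, on the local clock. The missing-value sentinel is the
literal string `NA` in every column that allows it. Booleans are
`true`/`false`. Files can be checked with `icuglucose validate <dir>`.

## stays.csv — one row per ICU stay

| column | type | notes |
|---|---|---|
| stay_id | id | unique per stay |
| patient_id | id | |
| admit_time | timestamp | |
| discharge_time | timestamp | must be after `admit_time` |
| is_readmission | bool | readmitted stays are excluded from the cohort |
| age_years | float ≥ 0 | |
| sex | `male` / `female` | |
| diabetes | bool | |
| race | label | free label, descriptive only |
| admission_type | `elective` / `emergency` | |
| sofa_admission | int ≥ 0 or `NA` | consumed as given, never computed |
| oasis | int ≥ 0 or `NA` | consumed as given |
| in_hospital_mortality | bool | |

## glucose_events.csv — timestamped glucose measurements

| column | type | notes |
|---|---|---|
| stay_id | id | |
| chart_time | timestamp | time of the data entry (proxy for sampling time) |
| store_time | timestamp or `NA` | time the caregiver recorded the value |
| value_mmol_l | float > 0 | glucose in mmol/L (mg/dL ÷ 18.016 ≈ × 0.0555) |
| sample_type | `whole_blood` / `serum` / `capillary` | drives validity limit and dedup preference |

The resolved measurement time is `min`-rule: `store_time` when it precedes
`chart_time`, else `chart_time`.

## nutrition_events.csv — enteral nutrition intervals

| column | type | notes |
|---|---|---|
| stay_id | id | |
| product_id | id | key into `products.csv` |
| start_time / end_time | timestamp | half-open interval `[start, end)`; `end ≥ start` |
| rate_ml_h | float ≥ 0 | pump rate |

## medication_events.csv — insulin / dextrose / glucocorticoid

| column | type | notes |
|---|---|---|
| stay_id | id | |
| kind | `insulin` / `dextrose` / `glucocorticoid` | |
| subtype | see below | |
| start_time / end_time | timestamp | `end ≥ start` (equal for pushes) |
| rate | float ≥ 0 or `NA` | units/h (insulin) or g/h (dextrose) |
| amount | float ≥ 0 or `NA` | units or g for discrete pushes |

`subtype` is the insulin action class (`rapid` / `short` / `intermediate` /
`long`), the dextrose mode (`infusion` / `push`), or empty for
glucocorticoids. Insulin and dextrose events carry exactly one of
`rate`/`amount`; glucocorticoids need neither (binary exposure).

## ventilation_events.csv / rass_events.csv — charted states

| column | type | notes |
|---|---|---|
| stay_id | id | |
| charted_time | timestamp | state is carried forward until the next record |
| ventilation | `invasive` / `non_invasive` / `none` | ventilation table only |
| rass | int −5..+4 or `NA` | RASS table only |

## products.csv — carbohydrate content lookup

| column | type | notes |
|---|---|---|
| product_id | id | |
| carb_g_ml | float ≥ 0 or `NA` | `NA` = unknown content; measurements covered only by such products are removed |

## analysis_table.csv — output of the matching stage

Fixed column order: `stay_id, resolved_time, glucose_mmol_l, hour_bin,
sample_type, age_years, age_cat, sex, diabetes, carb_rate_g_h, carb_cat,
insulin_rate_u_h, insulin_cat, dextrose_rate_g_h, dextrose_cat,
glucocorticoid, days_since_admission, time_to_next_sample_h, ventilation,
rass`. Category bands (upper bounds inclusive): carbohydrate ≤4.5 /
(4.5,6.5] / (6.5,8.5] / >8.5 g/h; insulin 0 / (0,1.5] / (1.5,3] / >3
units/h; dextrose 0 / (0,0.5] / (0.5,2] / >2 g/h; age <55 / 55–65 / 66–75 /
>75 years. `time_to_next_sample_h` and `rass` may be `NA`; everything else
is always present.
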