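"""Synthetic ICU cohorts with known ground truth.

The generator emits the full relational table bundle (stays, glucose,
nutrition, medication, ventilation and RASS events plus the product lookup)
so that every downstream stage — curation, exposure matching, modelling,
subgroup profiling — can be exercised end-to-end without external data.

Glucose is generated from the same structural model the pipeline fits::

    glucose = intercept
            + covariate effects of the *time-matched, PK-corrected* exposures
            + true hourly clock-time effect (reference hour 0 fixed at 0)
            + patient random intercept  ~ N(0, random_intercept_sd^2)
            + residual                  ~ N(0, residual_sd^2)

Default truth mirrors the adjusted-model estimates of the reference cohort:
intercept 6.6 mmol/L, diabetes +2.2, random-intercept variance 2.8, residual
variance 5.4, and a sinusoidal hourly effect of amplitude 0.5 mmol/L peaking
at 10:00 (about 1.0 mmol/L peak-to-trough).  Sampling times follow a uniform
base with Gaussian bumps at 04:00/10:00/16:00/22:00 emulating routine lab
rounds; the default sampling density of 4 measurements per ICU day matches
large real-world ICU cohorts.

Deliberate imperfections exercise the curation filters: a configurable
fraction of stays violates an inclusion criterion (short stay, readmission,
no enteral nutrition, no glucose), some glucose values exceed the validity
limits, and simultaneous same-time measurement pairs are injected.
Confounding schedules (diurnal dextrose infusions, day-high nutrition rates,
morning glucocorticoid courses) can be enabled to create a crude 24-h
pattern with a zero true clock-time effect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import TableBundle
from .match import build_effect_windows, match_exposures

#: adjusted-model coefficient truth (mmol/L), reference levels are 0
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "age[55-65]": 0.5,
    "age[66-75]": 0.6,
    "age[>75]": 0.6,
    "sex[male]": -0.2,
    "diabetes[True]": 2.2,
    "carb[4.5<x<=6.5]": 0.7,
    "carb[6.5<x<=8.5]": 1.0,
    "carb[>8.5]": 1.4,
    "insulin[0<x<=1.5]": 0.5,
    "insulin[1.5<x<=3]": 0.4,
    "insulin[>3]": -0.2,
    "dextrose[0<x<=0.5]": 0.1,
    "dextrose[0.5<x<=2]": 0.2,
    "dextrose[>2]": 0.6,
    "gc[True]": 1.0,
}


def _default_sampling_weights() -> np.ndarray:
    """Uniform base plus Gaussian bumps at the routine lab-round hours."""
    hours = np.arange(24, dtype=float)
    w = np.ones(24)
    for bump in (4, 10, 16, 22):
        d = np.minimum(np.abs(hours - bump), 24 - np.abs(hours - bump))
        w += 1.5 * np.exp(-0.5 * (d / 1.0) ** 2)
    return w / w.sum()


def sinusoid_time_effect(amplitude: float = 0.5, peak_hour: float = 10.0) -> np.ndarray:
    """Hourly clock-time effects from a 24-h sinusoid, re-anchored to hour 0.

    ``amplitude`` is the half peak-to-trough of the underlying sinusoid; the
    returned 24-vector is shifted so the reference hour 0 has effect exactly
    0, as in the dummy-coded model.
    """
    h = np.arange(24)
    raw = amplitude * np.cos(2 * np.pi * (h - peak_hour) / 24.0)
    return raw - raw[0]


@dataclass
class SynthConfig:
    """Generator configuration; defaults are the reference study conditions."""

    n_patients: int = 500
    seed: int = 0
    intercept: float = 6.6
    true_coefficients: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    #: explicit 24-vector of hourly effects (hour 0 must be 0) or None to use
    #: the sinusoid below
    true_time_effect: np.ndarray | None = None
    sinusoid_amplitude: float = 0.5
    sinusoid_peak_hour: float = 10.0
    random_intercept_sd: float = float(np.sqrt(2.8))
    residual_sd: float = float(np.sqrt(5.4))
    sampling_intensity_by_hour: np.ndarray = field(default_factory=_default_sampling_weights)
    samples_per_day: float = 4.0
    #: fraction of stays planted to violate one inclusion criterion
    violation_fraction: float = 0.15
    #: fraction of glucose values pushed above the validity limit
    invalid_value_fraction: float = 0.01
    #: fraction of measurements duplicated at the same instant with another
    #: sample type
    simultaneous_fraction: float = 0.02
    #: probability an enteral-nutrition run uses the unknown-content product
    unknown_product_fraction: float = 0.08
    n_products: int = 5
    #: multiplies the hourly effect per planted insulin-requirement tier
    tier_amplitude_scale: dict[str, float] = field(
        default_factory=lambda: {"none": 1.0, "low": 1.0, "mid": 1.0, "high": 1.0}
    )
    # confounding schedules (all off by default)
    diurnal_glucocorticoid: bool = False
    diurnal_dextrose: bool = False
    diurnal_nutrition: bool = False

    def resolved_time_effect(self) -> np.ndarray:
        if self.true_time_effect is not None:
            eff = np.asarray(self.true_time_effect, dtype=float)
            if eff.shape != (24,):
                raise ValueError("true_time_effect must have 24 entries")
            if eff[0] != 0.0:
                raise ValueError("reference hour 0 must have effect 0")
            return eff
        return sinusoid_time_effect(self.sinusoid_amplitude, self.sinusoid_peak_hour)

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.random_intercept_sd <= 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be positive")
        w = np.asarray(self.sampling_intensity_by_hour, dtype=float)
        if w.shape != (24,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("sampling_intensity_by_hour must be 24 non-negative weights")
        self.resolved_time_effect()


@dataclass
class GroundTruth:
    """What the generator actually realised, for recovery checks."""

    intercept: float
    coefficients: dict[str, float]
    hourly_effects: np.ndarray
    random_intercept_variance: float
    residual_variance: float
    patient_intercepts: dict[str, float]
    planted_violations: dict[str, str]
    planted_insulin_tier: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "hourly_effects": list(map(float, self.hourly_effects)),
            "random_intercept_variance": self.random_intercept_variance,
            "residual_variance": self.residual_variance,
            "patient_intercepts": self.patient_intercepts,
            "planted_violations": self.planted_violations,
            "planted_insulin_tier": self.planted_insulin_tier,
        }


_VIOLATION_KINDS = ("short_los", "readmission", "no_nutrition", "no_glucose")
_RACES = np.array(["white", "black", "hispanic", "asian", "other", "unknown"])
_RACE_P = np.array([0.61, 0.10, 0.04, 0.03, 0.04, 0.18])
_INSULIN_CLASSES = np.array(["rapid", "short", "intermediate", "long"])
_TIER_P = {"none": 0.30, "low": 0.40, "mid": 0.20, "high": 0.10}
_TIER_DAILY_UNITS = {"low": (5.0, 35.0), "mid": (36.0, 70.0), "high": (71.0, 140.0)}

_BASE_DATE = pd.Timestamp("2019-01-01")


def _minutes(ts: float) -> pd.Timestamp:
    """Hours-since-base offset rounded to a whole minute."""
    return _BASE_DATE + pd.Timedelta(minutes=round(ts * 60.0))


def generate_cohort(config: SynthConfig) -> tuple[TableBundle, GroundTruth]:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    hourly = config.resolved_time_effect()
    sampling_w = np.asarray(config.sampling_intensity_by_hour, dtype=float)
    sampling_w = sampling_w / sampling_w.sum()

    # product lookup: known-content products plus one of unknown content
    product_ids = [f"P{i:02d}" for i in range(1, config.n_products + 1)]
    contents = rng.uniform(0.10, 0.20, config.n_products).round(3)
    products = pd.DataFrame({
        "product_id": product_ids + ["P_UNK"],
        "carb_g_ml": list(contents) + [np.nan],
    })

    n_violate = int(round(config.violation_fraction * config.n_patients))
    violators = rng.choice(config.n_patients, size=n_violate, replace=False)
    violation_of = {int(i): _VIOLATION_KINDS[k % len(_VIOLATION_KINDS)] for k, i in enumerate(violators)}

    stays, glucose, nutrition, meds, vent, rass_rows = [], [], [], [], [], []
    patient_intercepts: dict[str, float] = {}
    planted_tier: dict[str, str] = {}
    planted_violations: dict[str, str] = {}
    sample_truth: list[tuple[str, float, int]] = []  # stay_id, time offset h, row index base

    tiers = list(_TIER_P)
    tier_draw = rng.choice(len(tiers), size=config.n_patients, p=list(_TIER_P.values()))

    for i in range(config.n_patients):
        stay_id = f"s{i:05d}"
        patient_id = f"p{i:05d}"
        violation = violation_of.get(i)
        if violation is not None:
            planted_violations[stay_id] = violation

        admit_h = float(rng.uniform(0, 24 * 60))
        los_days = float(rng.uniform(1.0, 3.9)) if violation == "short_los" else float(
            np.clip(rng.lognormal(np.log(9.0), 0.45), 4.2, 40.0)
        )
        los_h = los_days * 24.0
        discharge_h = admit_h + los_h

        b_i = float(rng.normal(0.0, config.random_intercept_sd))
        patient_intercepts[stay_id] = b_i
        age = int(rng.integers(30, 93))
        sex = "male" if rng.random() < 0.57 else "female"
        diabetes = bool(rng.random() < 0.31)
        stays.append({
            "stay_id": stay_id,
            "patient_id": patient_id,
            "admit_time": _minutes(admit_h),
            "discharge_time": _minutes(discharge_h),
            "is_readmission": violation == "readmission",
            "age_years": float(age),
            "sex": sex,
            "diabetes": diabetes,
            "race": str(rng.choice(_RACES, p=_RACE_P)),
            "admission_type": "elective" if rng.random() < 0.07 else "emergency",
            "sofa_admission": int(rng.poisson(8)) if rng.random() > 0.1 else None,
            "oasis": int(np.clip(rng.normal(40, 8), 10, 80)) if rng.random() > 0.1 else None,
            "in_hospital_mortality": bool(rng.random() < 0.28),
        })

        # --- enteral nutrition: piecewise-constant runs with interruptions.
        # Diurnal schedules apply to a random subset of patients: a confounder
        # aligned with clock time for *everyone* would be collinear with the
        # hour dummies and the adjusted model could not separate them.
        on_diurnal_nutrition = config.diurnal_nutrition and rng.random() < 0.6
        on_diurnal_dextrose = config.diurnal_dextrose and rng.random() < 0.6
        if violation != "no_nutrition":
            t = admit_h + float(rng.uniform(2, 12))
            while t < discharge_h - 1.0:
                if on_diurnal_nutrition:
                    dur = float(rng.uniform(3, 6))
                    hod = (t % 24.0)
                    rate = float(rng.uniform(65, 90)) if 8 <= hod < 20 else float(rng.uniform(15, 30))
                else:
                    dur = float(np.clip(rng.exponential(18.0), 4.0, 48.0))
                    rate = float(rng.uniform(30, 80))
                end = min(t + dur, discharge_h)
                pid = "P_UNK" if rng.random() < config.unknown_product_fraction else str(rng.choice(product_ids))
                nutrition.append({
                    "stay_id": stay_id, "product_id": pid,
                    "start_time": _minutes(t), "end_time": _minutes(end),
                    "rate_ml_h": round(rate, 1),
                })
                t = end + float(np.clip(rng.exponential(3.0), 0.5, 12.0))

        # --- insulin: planted requirement tier drives daily dosing
        tier = tiers[tier_draw[i]]
        total_units = 0.0
        if tier != "none":
            lo, hi = _TIER_DAILY_UNITS[tier]
            daily_units = float(rng.uniform(lo, hi))
            for day in range(int(np.ceil(los_days))):
                day_start = admit_h + day * 24.0
                span = min(24.0, discharge_h - day_start)
                if span <= 2.0:
                    continue
                units_today = daily_units * span / 24.0
                inf_units = units_today * float(rng.uniform(0.6, 0.9))
                dur = float(rng.uniform(min(4.0, span / 2), min(12.0, span)))
                start = day_start + float(rng.uniform(0, span - dur))
                meds.append({
                    "stay_id": stay_id, "kind": "insulin",
                    "subtype": str(rng.choice(_INSULIN_CLASSES[:2])),
                    "start_time": _minutes(start), "end_time": _minutes(start + dur),
                    "rate": round(inf_units / dur, 2), "amount": None,
                })
                total_units += round(inf_units / dur, 2) * dur
                bolus = units_today - inf_units
                if bolus > 1.0:
                    at = day_start + float(rng.uniform(0, span))
                    meds.append({
                        "stay_id": stay_id, "kind": "insulin",
                        "subtype": str(rng.choice(_INSULIN_CLASSES)),
                        "start_time": _minutes(at), "end_time": _minutes(at),
                        "rate": None, "amount": round(bolus, 1),
                    })
                    total_units += round(bolus, 1)
        planted_tier[stay_id] = tier

        # --- dextrose
        if on_diurnal_dextrose:
            for day in range(int(np.ceil(los_days))):
                if rng.random() < 0.4:  # schedule skips days, keeping it separable
                    continue
                start = (np.floor((admit_h + day * 24.0) / 24.0)) * 24.0 + 6.0
                if start < admit_h or start + 6.0 > discharge_h:
                    continue
                meds.append({
                    "stay_id": stay_id, "kind": "dextrose", "subtype": "infusion",
                    "start_time": _minutes(start), "end_time": _minutes(start + 6.0),
                    "rate": round(float(rng.uniform(3, 8)), 2), "amount": None,
                })
        else:
            for _ in range(rng.poisson(0.4 * los_days)):
                at = admit_h + float(rng.uniform(0, los_h))
                meds.append({
                    "stay_id": stay_id, "kind": "dextrose", "subtype": "push",
                    "start_time": _minutes(at), "end_time": _minutes(at),
                    "rate": None, "amount": round(float(rng.uniform(5, 25)), 1),
                })
            for _ in range(rng.poisson(0.15 * los_days)):
                at = admit_h + float(rng.uniform(0, los_h - 2))
                dur = float(rng.uniform(2, 8))
                meds.append({
                    "stay_id": stay_id, "kind": "dextrose", "subtype": "infusion",
                    "start_time": _minutes(at), "end_time": _minutes(min(at + dur, discharge_h)),
                    "rate": round(float(rng.uniform(1, 5)), 2), "amount": None,
                })

        # --- glucocorticoids
        if config.diurnal_glucocorticoid:
            if rng.random() < 0.4:
                first_day = int(rng.integers(0, max(1, int(los_days) - 1)))
                for day in range(first_day, min(first_day + int(rng.integers(1, 4)), int(los_days))):
                    start = np.floor((admit_h + day * 24.0) / 24.0) * 24.0 + 8.0
                    if start < admit_h or start > discharge_h - 1:
                        continue
                    meds.append({
                        "stay_id": stay_id, "kind": "glucocorticoid", "subtype": "",
                        "start_time": _minutes(start), "end_time": _minutes(start + 0.5),
                        "rate": None, "amount": None,
                    })
        elif rng.random() < 0.25:
            course_start = admit_h + float(rng.uniform(0, max(1.0, los_h - 48)))
            for day in range(int(rng.integers(1, 6))):
                at = course_start + day * 24.0 + float(rng.uniform(-2, 2))
                if at > discharge_h - 1:
                    break
                meds.append({
                    "stay_id": stay_id, "kind": "glucocorticoid", "subtype": "",
                    "start_time": _minutes(at), "end_time": _minutes(at + 0.5),
                    "rate": None, "amount": None,
                })

        # --- ventilation: state charted at admit, possible later transition
        r = rng.random()
        state = "invasive" if r < 0.90 else ("non_invasive" if r < 0.985 else "none")
        vent.append({"stay_id": stay_id, "charted_time": _minutes(admit_h), "ventilation": state})
        if state == "invasive" and rng.random() < 0.5:
            at = admit_h + los_h * float(rng.uniform(0.4, 0.9))
            vent.append({"stay_id": stay_id, "charted_time": _minutes(at), "ventilation": "none"})

        # --- RASS charted every ~8 h; deeper sedation early under ventilation
        n_rass = max(1, int(los_h / 8.0))
        for k in range(n_rass):
            at = admit_h + (k + rng.uniform(0, 0.5)) * 8.0
            if at >= discharge_h:
                break
            frac = (at - admit_h) / los_h
            mean = -3.0 if (state == "invasive" and frac < 0.5) else 0.0
            rass_rows.append({
                "stay_id": stay_id, "charted_time": _minutes(at),
                "rass": int(np.clip(round(rng.normal(mean, 1.0)), -5, 4)),
            })

        # --- glucose sampling times
        if violation != "no_glucose":
            n_samples = max(1, int(rng.poisson(config.samples_per_day * los_days)))
            days = rng.uniform(0, los_days, n_samples)
            hours_of_day = rng.choice(24, size=n_samples, p=sampling_w)
            minutes = rng.uniform(0, 60, n_samples)
            offsets = np.floor(admit_h / 24.0 + days) * 24.0 + hours_of_day + minutes / 60.0
            offsets = offsets[(offsets >= admit_h) & (offsets < discharge_h)]
            if offsets.size == 0:
                offsets = np.array([admit_h + los_h / 2.0])
            for t in offsets:
                sample_truth.append((stay_id, float(t), len(sample_truth)))

    stays_df = _typed_stays(stays)
    nutrition_df = _typed_events(nutrition, ["stay_id", "product_id", "start_time", "end_time", "rate_ml_h"])
    meds_df = _typed_events(meds, ["stay_id", "kind", "subtype", "start_time", "end_time", "rate", "amount"])
    vent_df = _typed_events(vent, ["stay_id", "charted_time", "ventilation"])
    rass_df = _typed_events(rass_rows, ["stay_id", "charted_time", "rass"])
    if len(rass_df):
        rass_df["rass"] = rass_df["rass"].astype("Int64")

    glucose_df = _generate_glucose(
        rng, config, hourly, sample_truth, stays_df, nutrition_df, meds_df, products,
        patient_intercepts, planted_tier,
    )

    bundle = TableBundle(
        stays=stays_df,
        glucose_events=glucose_df,
        nutrition_events=nutrition_df,
        medication_events=meds_df,
        ventilation_events=vent_df,
        rass_events=rass_df,
        products=products,
    )
    truth = GroundTruth(
        intercept=config.intercept,
        coefficients=dict(config.true_coefficients),
        hourly_effects=hourly,
        random_intercept_variance=config.random_intercept_sd**2,
        residual_variance=config.residual_sd**2,
        patient_intercepts=patient_intercepts,
        planted_violations=planted_violations,
        planted_insulin_tier=planted_tier,
    )
    return bundle, truth


def _typed_stays(records: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(records)
    for col in ("stay_id", "patient_id", "sex", "race", "admission_type"):
        df[col] = df[col].astype("string")
    for col in ("is_readmission", "diabetes", "in_hospital_mortality"):
        df[col] = df[col].astype("boolean")
    for col in ("sofa_admission", "oasis"):
        df[col] = df[col].astype("Int64")
    return df


def _typed_events(records: list[dict], columns: list[str]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=columns)
    for col in columns:
        if col in ("stay_id", "product_id", "kind", "subtype", "ventilation"):
            df[col] = df[col].astype("string")
        elif col.endswith("_time"):
            df[col] = pd.to_datetime(df[col])
        elif col in ("rate", "amount", "rate_ml_h"):
            df[col] = pd.to_numeric(df[col])
    return df


def _generate_glucose(
    rng, config, hourly, sample_truth, stays_df, nutrition_df, meds_df, products,
    patient_intercepts, planted_tier,
) -> pd.DataFrame:
    """Realise glucose values at the drawn sampling times.

    Values are computed from the true time-matched exposure state (using the
    same PK-corrected windows the pipeline applies), then chart/store times
    are arranged so timestamp resolution recovers the true sampling time.
    """
    from .datamodel import categorise_carb, categorise_dextrose, categorise_insulin, categorise_age

    if not sample_truth:
        return _typed_events([], ["stay_id", "chart_time", "store_time", "value_mmol_l", "sample_type"])
    base = pd.DataFrame({
        "stay_id": pd.array([s for s, _, _ in sample_truth], dtype="string"),
        "resolved_time": [_minutes(t) for _, t, _ in sample_truth],
    })
    windows = build_effect_windows(meds_df, nutrition_df, products)
    matched = match_exposures(base, windows)

    stay_info = stays_df.set_index("stay_id")
    age_cat = categorise_age(matched["stay_id"].map(stay_info["age_years"]).astype(float))
    coef = config.true_coefficients

    def level_effect(prefix: str, cats) -> np.ndarray:
        return np.array([coef.get(f"{prefix}[{c}]", 0.0) for c in np.asarray(cats)])

    eff = np.full(len(matched), config.intercept)
    eff += level_effect("age", age_cat)
    eff += np.where(matched["stay_id"].map(stay_info["sex"]).to_numpy() == "male", coef.get("sex[male]", 0.0), 0.0)
    eff += np.where(matched["stay_id"].map(stay_info["diabetes"]).astype(bool).to_numpy(), coef.get("diabetes[True]", 0.0), 0.0)
    eff += level_effect("carb", categorise_carb(matched["carb_rate_g_h"]))
    eff += level_effect("insulin", categorise_insulin(matched["insulin_rate_u_h"]))
    eff += level_effect("dextrose", categorise_dextrose(matched["dextrose_rate_g_h"]))
    eff += np.where(matched["glucocorticoid"].to_numpy(), coef.get("gc[True]", 0.0), 0.0)

    hour = pd.DatetimeIndex(matched["resolved_time"]).hour.to_numpy()
    tier_scale = matched["stay_id"].map(
        {k: config.tier_amplitude_scale.get(v, 1.0) for k, v in planted_tier.items()}
    ).to_numpy(dtype=float)
    eff += hourly[hour] * tier_scale
    eff += matched["stay_id"].map(patient_intercepts).to_numpy(dtype=float)
    values = eff + rng.normal(0.0, config.residual_sd, len(matched))
    values = np.maximum(values, 0.5).round(1)

    sample_type = rng.choice(
        np.array(["capillary", "whole_blood", "serum"]), size=len(matched), p=[0.60, 0.25, 0.15]
    )
    # push a configurable fraction above the validity limit of its assay
    invalid = rng.random(len(matched)) < config.invalid_value_fraction
    values = np.where(invalid & (sample_type == "capillary"), 27.9 + rng.random(len(matched)).round(1) * 5, values)
    values = np.where(invalid & (sample_type != "capillary"), 55.7 + rng.random(len(matched)).round(1) * 10, values)

    # chart/store arrangement: the resolved (min-rule) time equals the true time
    delta = pd.to_timedelta(np.round(rng.uniform(1, 30, len(matched))), unit="m")
    store_first = rng.random(len(matched)) < 0.10
    resolved = pd.DatetimeIndex(matched["resolved_time"])
    chart_time = pd.Series(np.where(store_first, resolved + delta, resolved))
    store_time = pd.Series(np.where(store_first, resolved, resolved + delta))
    store_missing = rng.random(len(matched)) < 0.2
    store_time[store_missing & ~store_first] = pd.NaT

    glucose = pd.DataFrame({
        "stay_id": matched["stay_id"].astype("string"),
        "chart_time": pd.to_datetime(chart_time),
        "store_time": pd.to_datetime(store_time),
        "value_mmol_l": values,
        "sample_type": pd.array(sample_type, dtype="string"),
    })

    # simultaneous measurement pairs: same resolved instant, other sample type
    n_dup = int(round(config.simultaneous_fraction * len(glucose)))
    if n_dup:
        pick = rng.choice(len(glucose), size=n_dup, replace=False)
        dup = glucose.iloc[pick].copy()
        other = {"capillary": "whole_blood", "whole_blood": "serum", "serum": "capillary"}
        dup["sample_type"] = dup["sample_type"].map(other).astype("string")
        dup["value_mmol_l"] = (
            dup["value_mmol_l"].to_numpy() + rng.normal(0, 0.3, n_dup)
        ).clip(0.5).round(1)
        glucose = pd.concat([glucose, dup], ignore_index=True)
    return glucose.sort_values(["stay_id", "chart_time"], kind="stable").reset_index(drop=True)


def generate_confounded_cohort(config: SynthConfig) -> tuple[TableBundle, GroundTruth]:
    """Cohort whose crude hourly profile is driven only by exposure schedules.

    Requires a zero true clock-time effect and at least one diurnal schedule
    flag; the crude hourly mean then shows 24-h structure that the adjusted
    model should remove.
    """
    if not (config.diurnal_glucocorticoid or config.diurnal_dextrose or config.diurnal_nutrition):
        raise ValueError("at least one diurnal confounding flag must be set")
    if np.any(config.resolved_time_effect() != 0.0):
        raise ValueError("confounded cohorts require a zero true time effect")
    return generate_cohort(config)


def null_config(**overrides) -> SynthConfig:
    """Config with zero hourly effect (covariate truth kept), for null studies."""
    defaults = dict(true_time_effect=np.zeros(24), sinusoid_amplitude=0.0)
    defaults.update(overrides)
    return SynthConfig(**defaults)


def config_from_dict(d: dict) -> SynthConfig:
    """Build a config from a plain (e.g. YAML-loaded) mapping."""
    known = {f.name for f in dataclasses.fields(SynthConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if "true_time_effect" in d and d["true_time_effect"] is not None:
        d = dict(d)
        d["true_time_effect"] = np.asarray(d["true_time_effect"], dtype=float)
    if "sampling_intensity_by_hour" in d:
        d = dict(d)
        d["sampling_intensity_by_hour"] = np.asarray(d["sampling_intensity_by_hour"], dtype=float)
    return SynthConfig(**d)
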