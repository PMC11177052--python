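"""Pharmacokinetic effect windows and the exposure-to-measurement join.

Administered exposures influence glucose beyond their charted interval, so
each event is first mapped to an *effect window*:

* insulin: start +0.5 h (onset delay); end extended by 2 / 4 / 10 / 12 h for
  rapid- / short- / intermediate- / long-acting classes;
* glucocorticoids: end extended by 24 h (sustained metabolic effect);
* dextrose pushes: a 10-minute window from the push time;
* dextrose infusions and enteral nutrition: the charted interval unchanged.

Windows are half-open ``[start, end)``.  A measurement is exposed to every
window containing its resolved time; concurrent windows of the same kind sum
their effective rates (additive administration), while glucocorticoid exposure
is a binary any-match flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    categorise_age,
    categorise_carb,
    categorise_dextrose,
    categorise_insulin,
    hour_of_day,
)

INSULIN_START_DELAY_H = 0.5
INSULIN_END_EXTENSION_H = {"rapid": 2.0, "short": 4.0, "intermediate": 10.0, "long": 12.0}
GLUCOCORTICOID_END_EXTENSION_H = 24.0
DEXTROSE_PUSH_WINDOW_MIN = 10.0


@dataclass(frozen=True)
class EffectWindow:
    """A corrected exposure interval with its constant effective rate.

    ``effective_rate`` is ``None`` for glucocorticoids (binary exposure).
    """

    stay_id: str
    kind: str
    window_start: pd.Timestamp
    window_end: pd.Timestamp
    effective_rate: float | None


def correct_window(event) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Corrected effect window of a single exposure event (pure).

    *event* is any mapping with ``kind``, ``subtype``, ``start_time`` and
    ``end_time`` fields (e.g. a DataFrame row).
    """
    kind = event["kind"]
    start, end = event["start_time"], event["end_time"]
    if kind == "insulin":
        cls = event["subtype"]
        if cls not in INSULIN_END_EXTENSION_H:
            raise ValueError(f"insulin event without a valid action class: {cls!r}")
        return (start + pd.Timedelta(hours=INSULIN_START_DELAY_H),
                end + pd.Timedelta(hours=INSULIN_END_EXTENSION_H[cls]))
    if kind == "glucocorticoid":
        return start, end + pd.Timedelta(hours=GLUCOCORTICOID_END_EXTENSION_H)
    if kind == "dextrose" and event["subtype"] == "push":
        return start, start + pd.Timedelta(minutes=DEXTROSE_PUSH_WINDOW_MIN)
    # dextrose infusion / enteral nutrition: charted interval unchanged
    return start, end


def effective_rate(event, window_start: pd.Timestamp, window_end: pd.Timestamp) -> float | None:
    """Constant rate attributed to the event over its corrected window.

    Infusions keep their recorded rate; discrete pushes/boluses spread their
    amount over the corrected window; glucocorticoids carry no rate (binary).
    """
    if event["kind"] == "glucocorticoid":
        return None
    rate, amount = event.get("rate"), event.get("amount")
    if rate is not None and not pd.isna(rate):
        return float(rate)
    hours = (window_end - window_start).total_seconds() / 3600.0
    if hours <= 0:
        raise ValueError("zero-duration window with a discrete amount")
    return float(amount) / hours


def carb_rate(rate_ml_h: float, content_g_ml: float) -> float:
    """Carbohydrate administration rate: nutrition rate x product content (g/h)."""
    return float(rate_ml_h) * float(content_g_ml)


def build_effect_windows(
    medications: pd.DataFrame, nutrition: pd.DataFrame, products: pd.DataFrame
) -> pd.DataFrame:
    """Vectorised window correction for all exposure events.

    Returns a frame with ``stay_id, kind, window_start, window_end,
    effective_rate``; nutrition events carry their carbohydrate rate (g/h,
    NaN when the product content is unknown) under kind
    ``enteral_nutrition``; glucocorticoid rows have NaN rate.
    """
    frames = []
    if len(medications):
        med = medications.copy()
        is_ins = med["kind"] == "insulin"
        is_gc = med["kind"] == "glucocorticoid"
        is_push = (med["kind"] == "dextrose") & (med["subtype"] == "push")
        start = med["start_time"] + pd.to_timedelta(
            np.where(is_ins, INSULIN_START_DELAY_H, 0.0), unit="h"
        )
        ext = np.zeros(len(med))
        ext[is_ins.to_numpy()] = med.loc[is_ins, "subtype"].map(INSULIN_END_EXTENSION_H).to_numpy()
        ext[is_gc.to_numpy()] = GLUCOCORTICOID_END_EXTENSION_H
        end = med["end_time"] + pd.to_timedelta(ext, unit="h")
        end = end.where(~is_push, med["start_time"] + pd.Timedelta(minutes=DEXTROSE_PUSH_WINDOW_MIN))
        hours = (end - start).dt.total_seconds() / 3600.0
        bad = med["amount"].notna() & (hours <= 0) & ~is_gc
        if bad.any():
            raise ValueError("zero-duration corrected window with a discrete amount")
        rate = med["rate"].astype(float)
        rate = rate.where(med["amount"].isna(), med["amount"].astype(float) / hours)
        rate = rate.where(~is_gc, np.nan)
        frames.append(pd.DataFrame({
            "stay_id": med["stay_id"],
            "kind": med["kind"],
            "window_start": start,
            "window_end": end,
            "effective_rate": rate,
        }))
    if len(nutrition):
        content = products.set_index("product_id")["carb_g_ml"]
        g_h = nutrition["rate_ml_h"].astype(float) * nutrition["product_id"].map(content).astype(float)
        frames.append(pd.DataFrame({
            "stay_id": nutrition["stay_id"],
            "kind": "enteral_nutrition",
            "window_start": nutrition["start_time"],
            "window_end": nutrition["end_time"],
            "effective_rate": g_h,
        }))
    if not frames:
        return pd.DataFrame(columns=["stay_id", "kind", "window_start", "window_end", "effective_rate"])
    return pd.concat(frames, ignore_index=True)


def _stab_sum(query_ns: np.ndarray, starts_ns: np.ndarray, ends_ns: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """Sum of rates of half-open intervals containing each query time.

    Event-boundary sweep: +rate at start, -rate at end, cumulative sum, then
    a searchsorted lookup.  A query equal to a start matches; equal to an end
    does not.
    """
    ev_t = np.concatenate([starts_ns, ends_ns])
    ev_d = np.concatenate([rates, -rates])
    order = np.argsort(ev_t, kind="stable")
    ev_t = ev_t[order]
    cum = np.cumsum(ev_d[order])
    idx = np.searchsorted(ev_t, query_ns, side="right")
    out = np.where(idx > 0, cum[np.maximum(idx - 1, 0)], 0.0)
    return np.maximum(out, 0.0)  # clamp float cancellation noise


def match_exposures(measurements: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Time-match summed exposure rates to each measurement.

    Adds ``carb_rate_g_h``, ``insulin_rate_u_h``, ``dextrose_rate_g_h``
    (sums over concurrent same-kind windows) and the binary
    ``glucocorticoid`` flag.  Nutrition windows with unknown carbohydrate
    content contribute no carbohydrate rate.
    """
    out = measurements.copy()
    n = len(out)
    cols = {"enteral_nutrition": "carb_rate_g_h", "insulin": "insulin_rate_u_h", "dextrose": "dextrose_rate_g_h"}
    for col in cols.values():
        out[col] = 0.0
    out["glucocorticoid"] = False
    if n == 0 or len(windows) == 0:
        return out

    t_all = out["resolved_time"].astype("datetime64[ns]").astype("int64").to_numpy()
    w_by_stay = {k: v for k, v in windows.groupby("stay_id", observed=True).indices.items()}
    for stay_id, m_idx in out.groupby("stay_id", observed=True).indices.items():
        w_idx = w_by_stay.get(stay_id)
        if w_idx is None:
            continue
        w = windows.iloc[w_idx]
        t = t_all[m_idx]
        for kind, col in cols.items():
            wk = w[w["kind"] == kind]
            if kind == "enteral_nutrition":
                wk = wk[wk["effective_rate"].notna()]
            if wk.empty:
                continue
            starts = wk["window_start"].astype("datetime64[ns]").astype("int64").to_numpy()
            ends = wk["window_end"].astype("datetime64[ns]").astype("int64").to_numpy()
            rates = wk["effective_rate"].to_numpy(dtype=float)
            out.iloc[m_idx, out.columns.get_loc(col)] = _stab_sum(t, starts, ends, rates)
        gc = w[w["kind"] == "glucocorticoid"]
        if not gc.empty:
            starts = gc["window_start"].astype("datetime64[ns]").astype("int64").to_numpy()
            ends = gc["window_end"].astype("datetime64[ns]").astype("int64").to_numpy()
            active = _stab_sum(t, starts, ends, np.ones(len(gc)))
            out.iloc[m_idx, out.columns.get_loc("glucocorticoid")] = active > 0.5
    return out


def derive_covariates(
    measurements: pd.DataFrame,
    stays: pd.DataFrame,
    all_glucose_times: pd.DataFrame,
    ventilation: pd.DataFrame,
    rass: pd.DataFrame,
) -> pd.DataFrame:
    """Derive per-measurement context covariates.

    ``days_since_admission`` from the stay's admit time;
    ``time_to_next_sample_h`` against *all* glucose measurements of the stay
    (including ones later excluded by the nutrition restriction), missing for
    the last sample; ventilation state and RASS carried forward from the most
    recent charted record at or before the measurement (ventilation defaults
    to ``none`` before any record; RASS stays missing).
    """
    out = measurements.copy()
    admit = stays.set_index("stay_id")["admit_time"]
    out["days_since_admission"] = (
        (out["resolved_time"] - out["stay_id"].map(admit)).dt.total_seconds() / 86400.0
    )

    # time to next sample: strictly-later nearest resolved time within the stay
    times_by_stay = {
        k: np.sort(v.astype("datetime64[ns]").astype("int64").to_numpy())
        for k, v in all_glucose_times.groupby("stay_id", observed=True)["resolved_time"]
    }
    t_ns = out["resolved_time"].astype("datetime64[ns]").astype("int64").to_numpy()
    ttn = np.full(len(out), np.nan)
    for stay_id, m_idx in out.groupby("stay_id", observed=True).indices.items():
        stay_times = times_by_stay.get(stay_id)
        if stay_times is None:
            continue
        pos = np.searchsorted(stay_times, t_ns[m_idx], side="right")
        has_next = pos < len(stay_times)
        nxt = stay_times[np.minimum(pos, len(stay_times) - 1)]
        ttn[m_idx] = np.where(has_next, (nxt - t_ns[m_idx]) / 3.6e12, np.nan)
    out["time_to_next_sample_h"] = ttn

    def _carry_forward(events: pd.DataFrame, value_col: str, default):
        if events.empty:
            return pd.Series([default] * len(out), index=out.index)
        sorted_out = out[["stay_id", "resolved_time"]].reset_index().sort_values("resolved_time", kind="stable")
        ev = events.sort_values("charted_time", kind="stable")
        merged = pd.merge_asof(
            sorted_out, ev.rename(columns={"charted_time": "resolved_time"}),
            on="resolved_time", by="stay_id", direction="backward",
        ).set_index("index").sort_index()
        return merged[value_col] if default is None else merged[value_col].fillna(default)

    out["ventilation"] = _carry_forward(ventilation, "ventilation", "none").to_numpy()
    out["rass"] = _carry_forward(rass, "rass", None).astype("Int64").to_numpy()
    return out


def build_analysis_table(bundle, curated_glucose: pd.DataFrame, included_stays: pd.Index) -> pd.DataFrame:
    """Assemble the modelling table from curated measurements and raw events.

    One row per curated glucose measurement carrying the time-matched
    exposure rates, their category bands, patient covariates and the derived
    context covariates, in the documented column order.
    """
    from .curate import add_resolved_time
    from .datamodel import ANALYSIS_COLUMNS

    stays = bundle.stays[bundle.stays["stay_id"].isin(included_stays)]
    meds = bundle.medication_events[bundle.medication_events["stay_id"].isin(included_stays)]
    nut = bundle.nutrition_events[bundle.nutrition_events["stay_id"].isin(included_stays)]
    windows = build_effect_windows(meds, nut, bundle.products)

    rows = curated_glucose.copy()
    if "resolved_time" not in rows.columns:
        rows = add_resolved_time(rows)
    rows = match_exposures(rows, windows)
    all_times = add_resolved_time(bundle.glucose_events)[["stay_id", "resolved_time"]]
    rows = derive_covariates(rows, stays, all_times, bundle.ventilation_events, bundle.rass_events)

    patient = stays.set_index("stay_id")
    rows["age_years"] = rows["stay_id"].map(patient["age_years"]).astype(float)
    rows["sex"] = rows["stay_id"].map(patient["sex"]).to_numpy()
    rows["diabetes"] = rows["stay_id"].map(patient["diabetes"]).astype(bool).to_numpy()
    rows["age_cat"] = categorise_age(rows["age_years"])
    rows["carb_cat"] = categorise_carb(rows["carb_rate_g_h"])
    rows["insulin_cat"] = categorise_insulin(rows["insulin_rate_u_h"])
    rows["dextrose_cat"] = categorise_dextrose(rows["dextrose_rate_g_h"])
    rows["glucose_mmol_l"] = rows["value_mmol_l"].astype(float)
    rows["hour_bin"] = hour_of_day(rows["resolved_time"])
    return rows[ANALYSIS_COLUMNS].reset_index(drop=True)
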