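"""Cohort selection and measurement-level cleaning.

The curation sequence mirrors the study design: ICU stays are kept when the
total length of stay is at least 4 days, the stay is not a readmission, and at
least one glucose measurement and one enteral-nutrition event fall within the
stay.  Measurement cleaning then runs validity filter -> simultaneous-sample
deduplication -> restriction to enteral-nutrition exposure, and every step's
in/out counts are recorded in a :class:`CurationReport` (the inclusion
flowchart).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import SAMPLE_TYPE_PREFERENCE, TableBundle, hour_of_day, length_of_stay_days

log = logging.getLogger(__name__)

#: accuracy limit of the laboratory analyser (whole blood / serum), mmol/L
LAB_VALIDITY_LIMIT_MMOL_L = 55.6
#: accuracy limit of point-of-care capillary glucometers, mmol/L
CAPILLARY_VALIDITY_LIMIT_MMOL_L = 27.8

#: minimum total ICU length of stay for inclusion, days
MIN_STAY_DAYS = 4.0


@dataclass
class CurationReport:
    """Counts in/out at each curation step plus per-row exclusion reasons."""

    steps: dict[str, tuple[int, int]] = field(default_factory=dict)
    exclusions: dict[str, int] = field(default_factory=dict)

    def record(self, step: str, rows_in: int, rows_out: int, reasons: dict[str, int] | None = None) -> None:
        if rows_out > rows_in:
            raise ValueError(f"step {step!r}: rows_out {rows_out} > rows_in {rows_in}")
        self.steps[step] = (rows_in, rows_out)
        for reason, n in (reasons or {}).items():
            self.exclusions[reason] = self.exclusions.get(reason, 0) + n

    def to_dict(self) -> dict:
        return {
            "steps": {k: {"rows_in": a, "rows_out": b} for k, (a, b) in self.steps.items()},
            "exclusions": dict(self.exclusions),
        }


def resolve_timestamps(glucose: pd.DataFrame) -> pd.Series:
    """Resolve the measurement timestamp from chart time and store time.

    The chart time is the best proxy for when the sample was actually taken,
    except when the store time (when the caregiver recorded the value)
    precedes it — then the store time is used.  A missing store time falls
    back to the chart time.
    """
    chart = glucose["chart_time"]
    store = glucose["store_time"]
    use_store = store.notna() & (store < chart)
    return chart.where(~use_store, store)


def add_resolved_time(glucose: pd.DataFrame) -> pd.DataFrame:
    """Attach ``resolved_time`` and ``hour_bin`` (hour rounded down, 0-23)."""
    out = glucose.copy()
    out["resolved_time"] = resolve_timestamps(out)
    out["hour_bin"] = hour_of_day(out["resolved_time"])
    return out


def select_cohort(
    stays: pd.DataFrame,
    glucose: pd.DataFrame,
    nutrition: pd.DataFrame,
    report: CurationReport | None = None,
) -> tuple[pd.Index, CurationReport]:
    """Apply the four stay-level inclusion criteria.

    Keeps stays with (1) length of stay >= 4 days, (2) no readmission,
    (3) >=1 glucose measurement during the stay and (4) >=1 enteral-nutrition
    event overlapping the stay.  "During the stay" means the resolved
    measurement time lies in ``[admit, discharge)``.
    """
    report = report or CurationReport()
    stays = stays.set_index("stay_id", drop=False)
    stays.index.name = None
    los_ok = length_of_stay_days(stays) >= MIN_STAY_DAYS
    not_readmit = ~stays["is_readmission"].astype(bool)

    g = add_resolved_time(glucose).merge(
        stays[["stay_id", "admit_time", "discharge_time"]], on="stay_id", how="inner"
    )
    in_stay = (g["resolved_time"] >= g["admit_time"]) & (g["resolved_time"] < g["discharge_time"])
    has_glucose = stays["stay_id"].isin(g.loc[in_stay, "stay_id"])

    nu = nutrition.merge(stays[["stay_id", "admit_time", "discharge_time"]], on="stay_id", how="inner")
    overlaps = (nu["start_time"] < nu["discharge_time"]) & (nu["end_time"] > nu["admit_time"])
    has_nutrition = stays["stay_id"].isin(nu.loc[overlaps, "stay_id"])

    keep = los_ok & not_readmit & has_glucose & has_nutrition
    reasons = {
        "stay_los_below_4_days": int((~los_ok).sum()),
        "stay_readmission": int((los_ok & ~not_readmit).sum()),
        "stay_no_glucose": int((los_ok & not_readmit & ~has_glucose).sum()),
        "stay_no_enteral_nutrition": int((los_ok & not_readmit & has_glucose & ~has_nutrition).sum()),
    }
    report.record("select_cohort", len(stays), int(keep.sum()), reasons)
    return stays.index[keep], report


def apply_validity_filter(
    glucose: pd.DataFrame, report: CurationReport | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, CurationReport]:
    """Drop measurements above the analyser accuracy limits.

    Capillary values > 27.8 mmol/L (500 mg/dL) and laboratory (whole blood or
    serum) values > 55.6 mmol/L (1000 mg/dL) are excluded; values exactly at
    a limit are kept.  Non-positive values are invalid input.
    """
    report = report or CurationReport()
    if (glucose["value_mmol_l"] <= 0).any():
        raise ValueError("non-positive glucose value; run datamodel validation first")
    cap = glucose["sample_type"] == "capillary"
    too_high = np.where(cap, glucose["value_mmol_l"] > CAPILLARY_VALIDITY_LIMIT_MMOL_L,
                        glucose["value_mmol_l"] > LAB_VALIDITY_LIMIT_MMOL_L)
    kept = glucose.loc[~too_high].reset_index(drop=True)
    dropped = glucose.loc[too_high].reset_index(drop=True)
    report.record(
        "validity_filter", len(glucose), len(kept),
        {"glucose_above_validity_limit": int(too_high.sum())},
    )
    return kept, dropped, report


def dedupe_simultaneous(
    glucose: pd.DataFrame, report: CurationReport | None = None
) -> tuple[pd.DataFrame, CurationReport]:
    """Keep one measurement per (stay, resolved time).

    Simultaneous measurements are resolved by sample-type preference:
    whole blood over serum over capillary.  A tie within the same sample type
    keeps the first row in input order and logs a warning.  Requires
    ``resolved_time`` (see :func:`add_resolved_time`); idempotent.
    """
    report = report or CurationReport()
    if "resolved_time" not in glucose.columns:
        raise ValueError("resolved_time missing; call add_resolved_time first")
    pref = glucose["sample_type"].map(SAMPLE_TYPE_PREFERENCE)
    order = np.lexsort((np.arange(len(glucose)), pref.to_numpy()))
    ranked = glucose.iloc[order]
    kept = ranked.drop_duplicates(subset=["stay_id", "resolved_time"], keep="first")
    same_type_ties = (
        glucose.groupby(["stay_id", "resolved_time", "sample_type"], observed=True).size() > 1
    )
    if same_type_ties.any():
        warnings.warn(
            f"{int(same_type_ties.sum())} (stay, time) groups had same-sample-type ties; kept first by input order",
            stacklevel=2,
        )
    kept = kept.sort_index().reset_index(drop=True)
    report.record(
        "dedupe_simultaneous", len(glucose), len(kept),
        {"glucose_simultaneous_duplicate": len(glucose) - len(kept)},
    )
    return kept, report


def restrict_to_enteral_nutrition(
    glucose: pd.DataFrame,
    nutrition: pd.DataFrame,
    products: pd.DataFrame,
    report: CurationReport | None = None,
) -> tuple[pd.DataFrame, CurationReport]:
    """Keep measurements taken while enteral nutrition was running.

    A measurement is kept when its resolved time falls inside at least one
    nutrition interval ``[start, end)`` of its stay.  Measurements covered
    only by products with unknown carbohydrate content are removed (their
    carbohydrate administration rate cannot be derived).
    """
    report = report or CurationReport()
    content = products.set_index("product_id")["carb_g_ml"]
    nut = nutrition.copy()
    nut["known_carb"] = nut["product_id"].map(content).notna().to_numpy()

    n_in = len(glucose)
    in_any = np.zeros(n_in, dtype=bool)
    in_known = np.zeros(n_in, dtype=bool)
    for stay_id, g_idx in glucose.groupby("stay_id", observed=True).indices.items():
        runs = nut[nut["stay_id"] == stay_id]
        if runs.empty:
            continue
        t = glucose["resolved_time"].to_numpy()[g_idx]
        starts = runs["start_time"].to_numpy()
        ends = runs["end_time"].to_numpy()
        known = runs["known_carb"].to_numpy()
        inside = (t[:, None] >= starts[None, :]) & (t[:, None] < ends[None, :])
        in_any[g_idx] = inside.any(axis=1)
        in_known[g_idx] = (inside & known[None, :]).any(axis=1)

    kept = glucose.loc[in_known].reset_index(drop=True)
    report.record(
        "restrict_to_enteral_nutrition", n_in, len(kept),
        {
            "glucose_outside_enteral_nutrition": int((~in_any).sum()),
            "glucose_unknown_carb_content_only": int((in_any & ~in_known).sum()),
        },
    )
    return kept, report


def curate(bundle: TableBundle) -> tuple[pd.DataFrame, pd.Index, CurationReport]:
    """Full curation: cohort selection then the measurement-cleaning chain.

    Returns the curated glucose table (with ``resolved_time``/``hour_bin``),
    the included stay ids, and the step-by-step report.
    """
    report = CurationReport()
    included, report = select_cohort(bundle.stays, bundle.glucose_events, bundle.nutrition_events, report)
    g = add_resolved_time(bundle.glucose_events)
    g = g[g["stay_id"].isin(included)].reset_index(drop=True)
    stays_idx = bundle.stays.set_index("stay_id")
    g = g.merge(stays_idx[["admit_time", "discharge_time"]], on="stay_id", how="left")
    in_stay = (g["resolved_time"] >= g["admit_time"]) & (g["resolved_time"] < g["discharge_time"])
    report.record("measurements_in_included_stays", len(g), int(in_stay.sum()),
                  {"glucose_outside_stay_window": int((~in_stay).sum())})
    g = g.loc[in_stay].drop(columns=["admit_time", "discharge_time"]).reset_index(drop=True)
    g, _, report = apply_validity_filter(g, report)
    g, report = dedupe_simultaneous(g, report)
    nut = bundle.nutrition_events[bundle.nutrition_events["stay_id"].isin(included)]
    g, report = restrict_to_enteral_nutrition(g, nut, bundle.products, report)
    return g, included, report
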