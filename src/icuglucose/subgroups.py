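"""Subgroup construction and per-subgroup 24-h profiles.

Sensitivity analyses refit the final model specification within subgroups
defined by variables with an indirect or potentially biasing influence on
glucose: ventilation mode, in-hospital mortality, sedation depth (RASS <= -2
as the sedation proxy), days in ICU, sample type, sampling frequency (time
to the next sample) and stay-level insulin requirement.  Each axis
partitions the rows with non-missing axis data; each level gets its own
model-4 fit and EMM profile, and levels that cannot support the fit (fewer
than 2 patients, or an empty hour bin) are reported as skipped rather than
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .datamodel import length_of_stay_days
from .models import EmmProfile, emm_profile, fit_model

INSULIN_TIERS = ("none", "low", "mid", "high")
#: average daily insulin bands (units/day): (0,35] low, (35,70] mid, >70 high
INSULIN_TIER_EDGES = (35.0, 70.0)

#: default bins for axes whose edges are conventions, config-overridable
ICU_DAY_BINS = ((0.0, 3.0), (3.0, 7.0), (7.0, np.inf))
ICU_DAY_LABELS = ("day 1-3", "day 4-7", "day >=8")
TIME_TO_NEXT_BINS = ((0.0, 2.0), (2.0, 6.0), (6.0, np.inf))
TIME_TO_NEXT_LABELS = ("<=2 h", "2-6 h", ">6 h")


def total_insulin_units(medications: pd.DataFrame) -> pd.Series:
    """Total insulin units administered per stay, from raw events.

    Infusions contribute rate x raw charted duration; pushes contribute their
    amount.  Totals use the uncorrected intervals: the PK window corrections
    model effect persistence, not the delivered dose.
    """
    ins = medications[medications["kind"] == "insulin"]
    if ins.empty:
        return pd.Series(dtype=float)
    hours = (ins["end_time"] - ins["start_time"]).dt.total_seconds() / 3600.0
    units = np.where(ins["rate"].notna(), ins["rate"].astype(float) * hours, ins["amount"].astype(float))
    if (units < 0).any():
        raise ValueError("negative insulin totals")
    return pd.Series(units).groupby(ins["stay_id"].to_numpy()).sum()


def assign_insulin_tier(stays: pd.DataFrame, medications: pd.DataFrame) -> pd.Series:
    """Stay-level insulin-requirement tier from average daily units.

    ``none`` = no insulin at any point; then (0,35] -> low, (35,70] -> mid,
    >70 units/day -> high, with the stay's total units averaged over its
    length of stay.
    """
    totals = total_insulin_units(medications)
    los = length_of_stay_days(stays.set_index("stay_id"))
    daily = (totals.reindex(los.index).fillna(0.0) / los).astype(float)
    lo, hi = INSULIN_TIER_EDGES
    labels = np.select(
        [daily.to_numpy() == 0.0, daily.to_numpy() <= lo, daily.to_numpy() <= hi],
        ["none", "low", "mid"],
        default="high",
    )
    return pd.Series(labels, index=los.index, name="insulin_tier")


@dataclass
class SubgroupSpec:
    """One level of a subgroup axis: a named row predicate."""

    axis: str
    level: str
    predicate: Callable[[pd.DataFrame], pd.Series]


def default_subgroup_specs(stays: pd.DataFrame, medications: pd.DataFrame) -> list[SubgroupSpec]:
    """All levels of every default axis, as row predicates over the analysis table."""
    tier = assign_insulin_tier(stays, medications)
    mort = stays.set_index("stay_id")["in_hospital_mortality"]
    specs: list[SubgroupSpec] = []
    for level in ("invasive", "non_invasive", "none"):
        specs.append(SubgroupSpec("ventilation", level, lambda r, lv=level: r["ventilation"] == lv))
    for level, flag in (("died", True), ("survived", False)):
        specs.append(SubgroupSpec("mortality", level, lambda r, f=flag: r["stay_id"].map(mort).astype(bool) == f))
    specs.append(SubgroupSpec("rass", "sedated (<= -2)", lambda r: r["rass"].notna() & (r["rass"] <= -2)))
    specs.append(SubgroupSpec("rass", "not sedated (> -2)", lambda r: r["rass"].notna() & (r["rass"] > -2)))
    for (lo, hi), label in zip(ICU_DAY_BINS, ICU_DAY_LABELS):
        specs.append(SubgroupSpec(
            "icu_day", label,
            lambda r, lo=lo, hi=hi: (r["days_since_admission"] >= lo) & (r["days_since_admission"] < hi),
        ))
    for level in ("whole_blood", "serum", "capillary"):
        specs.append(SubgroupSpec("sample_type", level, lambda r, lv=level: r["sample_type"] == lv))
    for (lo, hi), label in zip(TIME_TO_NEXT_BINS, TIME_TO_NEXT_LABELS):
        specs.append(SubgroupSpec(
            "sampling_frequency", label,
            lambda r, lo=lo, hi=hi: r["time_to_next_sample_h"].notna()
            & (r["time_to_next_sample_h"] > lo) & (r["time_to_next_sample_h"] <= hi),
        ))
    for level in INSULIN_TIERS:
        specs.append(SubgroupSpec("insulin_requirement", level, lambda r, lv=level: r["stay_id"].map(tier) == lv))
    return specs


@dataclass
class SubgroupResult:
    axis: str
    level: str
    n_rows: int
    n_patients: int
    profile: EmmProfile | None
    skipped_reason: str | None = None


def run_subgroup_analysis(
    rows: pd.DataFrame, specs: list[SubgroupSpec], weighting: str = "equal"
) -> list[SubgroupResult]:
    """Fit the final-model specification within each subgroup level.

    Each subgroup's ML fit feeds its EMM profile.  Levels with fewer than 2
    patients or any unpopulated hour bin are recorded as skipped.
    """
    results: list[SubgroupResult] = []
    for spec in specs:
        mask = spec.predicate(rows).fillna(False).to_numpy(dtype=bool)
        sub = rows.loc[mask]
        n_pat = int(sub["stay_id"].nunique())
        if n_pat < 2:
            results.append(SubgroupResult(spec.axis, spec.level, len(sub), n_pat, None, "fewer than 2 patients"))
            continue
        hours_present = set(sub["hour_bin"].unique())
        missing_hours = sorted(set(range(24)) - hours_present)
        if missing_hours:
            results.append(SubgroupResult(
                spec.axis, spec.level, len(sub), n_pat, None,
                f"unpopulated hour bin(s): {missing_hours}",
            ))
            continue
        fit = fit_model(sub, "m4", reml=False)
        results.append(SubgroupResult(spec.axis, spec.level, len(sub), n_pat, emm_profile(fit, sub, weighting)))
    return results


def subgroup_counts(results: list[SubgroupResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "axis": r.axis, "level": r.level, "n_rows": r.n_rows, "n_patients": r.n_patients,
            "fitted": r.profile is not None, "skipped_reason": r.skipped_reason or "",
        }
        for r in results
    ])
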