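"""Timestamp resolution, validity limits, deduplication and cohort filters."""

import numpy as np
import pandas as pd
import pytest

from icuglucose import curate as cu
from icuglucose.datamodel import SAMPLE_TYPE_PREFERENCE

T = pd.Timestamp


def _glucose(rows):
    df = pd.DataFrame(rows, columns=["stay_id", "chart_time", "store_time", "value_mmol_l", "sample_type"])
    df["chart_time"] = pd.to_datetime(df["chart_time"])
    df["store_time"] = pd.to_datetime(df["store_time"])
    return df


class TestResolveTimestamps:
    def test_store_before_chart_wins(self):
        g = _glucose([("s1", "2019-01-01T10:00:00", "2019-01-01T09:45:00", 8.0, "serum")])
        assert cu.resolve_timestamps(g).iloc[0] == T("2019-01-01T09:45:00")

    def test_store_after_chart_keeps_chart(self):
        g = _glucose([("s1", "2019-01-01T10:00:00", "2019-01-01T10:30:00", 8.0, "serum")])
        assert cu.resolve_timestamps(g).iloc[0] == T("2019-01-01T10:00:00")

    def test_missing_store_falls_back_to_chart(self):
        g = _glucose([("s1", "2019-01-01T10:00:00", None, 8.0, "serum")])
        assert cu.resolve_timestamps(g).iloc[0] == T("2019-01-01T10:00:00")


class TestValidityFilter:
    def test_capillary_grid_max_kept_is_27_8(self):
        values = np.round(np.arange(25.0, 30.01, 0.1), 1)
        g = _glucose([("s1", "2019-01-01T10:00:00", None, v, "capillary") for v in values])
        kept, dropped, _ = cu.apply_validity_filter(g)
        assert kept["value_mmol_l"].max() == 27.8
        assert dropped["value_mmol_l"].min() == pytest.approx(27.9)

    def test_lab_grid_max_kept_is_55_6(self):
        values = np.round(np.arange(54.0, 57.01, 0.1), 1)
        for st in ("whole_blood", "serum"):
            g = _glucose([("s1", "2019-01-01T10:00:00", None, v, st) for v in values])
            kept, _, _ = cu.apply_validity_filter(g)
            assert kept["value_mmol_l"].max() == 55.6

    def test_serum_30_kept(self):
        g = _glucose([("s1", "2019-01-01T10:00:00", None, 30.0, "serum")])
        kept, _, _ = cu.apply_validity_filter(g)
        assert len(kept) == 1

    def test_non_positive_value_raises(self):
        g = _glucose([("s1", "2019-01-01T10:00:00", None, 0.0, "serum")])
        with pytest.raises(ValueError, match="non-positive"):
            cu.apply_validity_filter(g)


class TestDedupeSimultaneous:
    def _resolved(self, rows):
        return cu.add_resolved_time(_glucose(rows))

    def test_whole_blood_preferred_over_capillary(self):
        g = self._resolved([
            ("s1", "2019-01-01T10:00:00", None, 7.5, "capillary"),
            ("s1", "2019-01-01T10:00:00", None, 8.0, "whole_blood"),
        ])
        kept, _ = cu.dedupe_simultaneous(g)
        assert len(kept) == 1 and kept.loc[0, "value_mmol_l"] == 8.0

    def test_single_measurement_unchanged_and_idempotent(self):
        g = self._resolved([("s1", "2019-01-01T10:00:00", None, 8.0, "serum")])
        once, _ = cu.dedupe_simultaneous(g)
        twice, _ = cu.dedupe_simultaneous(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_random_groups_match_bruteforce_preference_oracle(self):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(400):
            stay = f"s{rng.integers(5)}"
            t = f"2019-01-01T{rng.integers(24):02d}:{rng.integers(4) * 15:02d}:00"
            st = ["whole_blood", "serum", "capillary"][rng.integers(3)]
            rows.append((stay, t, None, round(float(rng.uniform(4, 12)), 1), st))
        g = self._resolved(rows)
        with pytest.warns(UserWarning, match="same-sample-type ties"):
            kept, _ = cu.dedupe_simultaneous(g)
        # oracle: best-preference row per group, first by input order on ties
        expect = {}
        for idx, row in g.iterrows():
            key = (row["stay_id"], row["resolved_time"])
            if key not in expect or SAMPLE_TYPE_PREFERENCE[row["sample_type"]] < SAMPLE_TYPE_PREFERENCE[expect[key][1]]:
                expect[key] = (idx, row["sample_type"])
        oracle = g.loc[sorted(i for i, _ in expect.values())].reset_index(drop=True)
        pd.testing.assert_frame_equal(kept, oracle)

    def test_permutation_invariance_across_sample_types(self):
        rows = [
            ("s1", "2019-01-01T10:00:00", None, 7.5, "capillary"),
            ("s1", "2019-01-01T10:00:00", None, 8.0, "whole_blood"),
            ("s1", "2019-01-01T10:00:00", None, 7.8, "serum"),
        ]
        kept_fwd, _ = cu.dedupe_simultaneous(self._resolved(rows))
        kept_rev, _ = cu.dedupe_simultaneous(self._resolved(rows[::-1]))
        assert kept_fwd.loc[0, "value_mmol_l"] == kept_rev.loc[0, "value_mmol_l"] == 8.0


class TestSelectCohort:
    def _stays(self, los_days, readmit=False):
        return pd.DataFrame({
            "stay_id": ["s1"], "patient_id": ["p1"],
            "admit_time": [T("2019-01-01T00:00:00")],
            "discharge_time": [T("2019-01-01T00:00:00") + pd.Timedelta(days=los_days)],
            "is_readmission": [readmit],
        })

    def _events(self):
        glucose = _glucose([("s1", "2019-01-02T10:00:00", None, 8.0, "serum")])
        nutrition = pd.DataFrame({
            "stay_id": ["s1"], "product_id": ["P01"],
            "start_time": [T("2019-01-01T06:00:00")], "end_time": [T("2019-01-03T06:00:00")],
            "rate_ml_h": [50.0],
        })
        return glucose, nutrition

    def test_los_3_9_excluded_4_0_included(self):
        glucose, nutrition = self._events()
        short, _ = cu.select_cohort(self._stays(3.9), glucose, nutrition)
        exact, _ = cu.select_cohort(self._stays(4.0), glucose, nutrition)
        assert list(short) == [] and list(exact) == ["s1"]

    def test_readmission_excluded(self):
        glucose, nutrition = self._events()
        kept, report = cu.select_cohort(self._stays(5.0, readmit=True), glucose, nutrition)
        assert list(kept) == [] and report.exclusions["stay_readmission"] == 1


class TestEnteralNutritionRestriction:
    def _setup(self):
        nutrition = pd.DataFrame({
            "stay_id": ["s1", "s1"],
            "product_id": ["P01", "P_UNK"],
            "start_time": pd.to_datetime(["2019-01-01T08:00:00", "2019-01-01T20:00:00"]),
            "end_time": pd.to_datetime(["2019-01-01T12:00:00", "2019-01-01T23:00:00"]),
            "rate_ml_h": [50.0, 50.0],
        })
        products = pd.DataFrame({"product_id": ["P01", "P_UNK"], "carb_g_ml": [0.14, np.nan]})
        return nutrition, products

    @pytest.mark.parametrize(
        "time,kept",
        [
            ("2019-01-01T07:59:00", False),  # one minute before the run starts
            ("2019-01-01T08:00:00", True),   # at start: half-open interval includes it
            ("2019-01-01T10:00:00", True),
            ("2019-01-01T12:00:00", False),  # at end: excluded
            ("2019-01-01T21:00:00", False),  # covered only by unknown-content product
        ],
    )
    def test_interval_and_unknown_content_rules(self, time, kept):
        nutrition, products = self._setup()
        g = cu.add_resolved_time(_glucose([("s1", time, None, 8.0, "serum")]))
        out, _ = cu.restrict_to_enteral_nutrition(g, nutrition, products)
        assert (len(out) == 1) is kept


def test_step_counts_compose(small_cohort):
    report = small_cohort[4]
    steps = list(report.steps.values())
    for (_, out_prev), (in_next, _) in zip(steps[1:-1], steps[2:]):
        assert out_prev == in_next
    for rows_in, rows_out in steps:
        assert rows_out <= rows_in
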