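"""Effect-window corrections and the exposure-measurement temporal join."""

import numpy as np
import pandas as pd
import pytest

from icuglucose import match as mt
from icuglucose.synth import SynthConfig, generate_cohort

T = pd.Timestamp


def _event(kind, subtype, start, end, rate=None, amount=None, stay="s1"):
    return {
        "stay_id": stay, "kind": kind, "subtype": subtype,
        "start_time": T(start), "end_time": T(end), "rate": rate, "amount": amount,
    }


class TestCorrectWindow:
    @pytest.mark.parametrize(
        "cls,expected_end",
        [("rapid", "2019-01-01T11:00:00"), ("short", "2019-01-01T13:00:00"),
         ("intermediate", "2019-01-01T19:00:00"), ("long", "2019-01-01T21:00:00")],
    )
    def test_insulin_start_delay_and_class_extension(self, cls, expected_end):
        start, end = mt.correct_window(_event("insulin", cls, "2019-01-01T08:00:00", "2019-01-01T09:00:00", rate=2))
        assert start == T("2019-01-01T08:30:00")
        assert end == T(expected_end)

    def test_glucocorticoid_24h_extension(self):
        start, end = mt.correct_window(_event("glucocorticoid", "", "2019-01-01T10:00:00", "2019-01-01T10:30:00"))
        assert start == T("2019-01-01T10:00:00")
        assert end == T("2019-01-02T10:30:00")

    def test_dextrose_push_10min_window(self):
        start, end = mt.correct_window(_event("dextrose", "push", "2019-01-01T10:15:00", "2019-01-01T10:15:00", amount=5))
        assert (start, end) == (T("2019-01-01T10:15:00"), T("2019-01-01T10:25:00"))

    def test_dextrose_infusion_unchanged(self):
        e = _event("dextrose", "infusion", "2019-01-01T10:00:00", "2019-01-01T14:00:00", rate=3)
        assert mt.correct_window(e) == (e["start_time"], e["end_time"])

    def test_insulin_without_class_raises(self):
        with pytest.raises(ValueError, match="action class"):
            mt.correct_window(_event("insulin", "", "2019-01-01T08:00:00", "2019-01-01T09:00:00", rate=2))


class TestEffectiveRate:
    def test_push_amount_spread_over_window(self):
        e = _event("dextrose", "push", "2019-01-01T10:15:00", "2019-01-01T10:15:00", amount=5)
        ws, we = mt.correct_window(e)
        assert mt.effective_rate(e, ws, we) == pytest.approx(30.0)  # 5 g over 10 min

    def test_infusion_rate_passthrough(self):
        e = _event("insulin", "short", "2019-01-01T08:00:00", "2019-01-01T09:00:00", rate=2.0)
        assert mt.effective_rate(e, *mt.correct_window(e)) == 2.0

    def test_glucocorticoid_has_no_rate(self):
        e = _event("glucocorticoid", "", "2019-01-01T10:00:00", "2019-01-01T10:30:00")
        assert mt.effective_rate(e, *mt.correct_window(e)) is None


def test_carb_rate_arithmetic():
    assert mt.carb_rate(50.0, 0.14) == pytest.approx(7.0)
    assert mt.carb_rate(0.0, 0.14) == 0.0
    rng = np.random.default_rng(0)
    for _ in range(100):
        r, c = rng.uniform(0, 100), rng.uniform(0.05, 0.3)
        assert mt.carb_rate(r, c) == pytest.approx(r * c)


def _windows(rows):
    return pd.DataFrame(rows, columns=["stay_id", "kind", "window_start", "window_end", "effective_rate"]).assign(
        window_start=lambda d: pd.to_datetime(d["window_start"]),
        window_end=lambda d: pd.to_datetime(d["window_end"]),
    )


def _measurements(times, stay="s1"):
    return pd.DataFrame({"stay_id": stay, "resolved_time": pd.to_datetime(times)})


class TestMatchExposures:
    def test_concurrent_insulin_windows_sum(self):
        w = _windows([
            ("s1", "insulin", "2019-01-01T08:00:00", "2019-01-01T12:00:00", 1.0),
            ("s1", "insulin", "2019-01-01T09:00:00", "2019-01-01T11:00:00", 2.0),
        ])
        out = mt.match_exposures(_measurements(["2019-01-01T10:00:00"]), w)
        assert out.loc[0, "insulin_rate_u_h"] == pytest.approx(3.0)

    def test_outside_all_windows_is_zero(self):
        w = _windows([("s1", "insulin", "2019-01-01T08:00:00", "2019-01-01T09:00:00", 1.0)])
        out = mt.match_exposures(_measurements(["2019-01-01T20:00:00"]), w)
        assert out.loc[0, "insulin_rate_u_h"] == 0.0
        assert not out.loc[0, "glucocorticoid"]

    def test_half_open_boundaries(self):
        w = _windows([("s1", "insulin", "2019-01-01T08:00:00", "2019-01-01T09:00:00", 1.0)])
        out = mt.match_exposures(_measurements(["2019-01-01T08:00:00", "2019-01-01T09:00:00"]), w)
        assert list(out["insulin_rate_u_h"]) == [1.0, 0.0]

    def test_minute_scan_oracle_equivalence_on_random_stays(self):
        """Summed matched rates equal a brute-force per-minute active-window scan."""
        rng = np.random.default_rng(11)
        base = T("2019-01-01T00:00:00")
        kinds = ["insulin", "dextrose", "enteral_nutrition", "glucocorticoid"]
        wrows, mrows = [], []
        for s in range(12):
            stay = f"s{s}"
            for _ in range(rng.integers(3, 15)):
                kind = kinds[rng.integers(4)]
                start = int(rng.integers(0, 5000))
                end = start + int(rng.integers(10, 2000))
                rate = np.nan if kind == "glucocorticoid" else round(float(rng.uniform(0.5, 5)), 2)
                wrows.append((stay, kind, base + pd.Timedelta(minutes=start), base + pd.Timedelta(minutes=end), rate))
            for _ in range(40):
                mrows.append((stay, base + pd.Timedelta(minutes=int(rng.integers(0, 7000)))))
        windows = _windows(wrows)
        meas = pd.DataFrame(mrows, columns=["stay_id", "resolved_time"])
        out = mt.match_exposures(meas, windows)

        col_of = {"insulin": "insulin_rate_u_h", "dextrose": "dextrose_rate_g_h", "enteral_nutrition": "carb_rate_g_h"}
        for i, m in meas.iterrows():
            active = windows[
                (windows["stay_id"] == m["stay_id"])
                & (windows["window_start"] <= m["resolved_time"])
                & (m["resolved_time"] < windows["window_end"])
            ]
            for kind, col in col_of.items():
                expect = active.loc[active["kind"] == kind, "effective_rate"].sum()
                assert out.loc[i, col] == pytest.approx(expect, abs=1e-9), (i, kind)
            assert out.loc[i, "glucocorticoid"] == bool((active["kind"] == "glucocorticoid").any())

    def test_extending_a_window_never_loses_matches(self):
        rng = np.random.default_rng(3)
        w = _windows([("s1", "insulin", "2019-01-01T06:00:00", "2019-01-01T10:00:00", 1.0)])
        times = [T("2019-01-01T00:00:00") + pd.Timedelta(minutes=int(m)) for m in rng.integers(0, 24 * 60, 200)]
        n_before = (mt.match_exposures(_measurements(times), w)["insulin_rate_u_h"] > 0).sum()
        w2 = w.copy()
        w2["window_end"] += pd.Timedelta(hours=4)
        n_after = (mt.match_exposures(_measurements(times), w2)["insulin_rate_u_h"] > 0).sum()
        assert n_after >= n_before


class TestStabSumProperty:
    """Property check of the interval-stabbing kernel behind the join."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    intervals = st.lists(
        st.tuples(st.integers(0, 500), st.integers(1, 200), st.floats(0.1, 10.0)),
        min_size=0, max_size=20,
    )
    queries = st.lists(st.integers(0, 800), min_size=1, max_size=30)

    @given(intervals=intervals, queries=queries)
    @settings(max_examples=150, deadline=None)
    def test_sum_of_half_open_intervals(self, intervals, queries):
        import numpy as np

        from icuglucose.match import _stab_sum

        starts = np.array([s for s, _, _ in intervals], dtype=np.int64)
        ends = np.array([s + d for s, d, _ in intervals], dtype=np.int64)
        rates = np.array([r for _, _, r in intervals])
        q = np.array(queries, dtype=np.int64)
        got = _stab_sum(q, starts, ends, rates) if len(intervals) else np.zeros(len(q))
        expect = [
            sum(r for s, d, r in intervals if s <= t < s + d) for t in queries
        ]
        assert got == pytest.approx(expect, abs=1e-9)


class TestDeriveCovariates:
    def _stays(self):
        return pd.DataFrame({
            "stay_id": ["s1"],
            "admit_time": [T("2019-01-07T00:00:00")],  # a Monday
            "discharge_time": [T("2019-01-17T00:00:00")],
        })

    def test_days_since_admission(self):
        meas = _measurements(["2019-01-09T12:00:00"])  # Wednesday noon
        out = mt.derive_covariates(meas, self._stays(), meas, pd.DataFrame(columns=["stay_id", "charted_time", "ventilation"]), pd.DataFrame(columns=["stay_id", "charted_time", "rass"]))
        assert out.loc[0, "days_since_admission"] == pytest.approx(2.5)

    def test_time_to_next_sample_uses_all_measurements(self):
        meas = _measurements(["2019-01-09T12:00:00"])
        all_times = _measurements(["2019-01-09T12:00:00", "2019-01-09T13:30:00"])
        out = mt.derive_covariates(meas, self._stays(), all_times, pd.DataFrame(columns=["stay_id", "charted_time", "ventilation"]), pd.DataFrame(columns=["stay_id", "charted_time", "rass"]))
        assert out.loc[0, "time_to_next_sample_h"] == pytest.approx(1.5)

    def test_last_sample_has_missing_time_to_next(self):
        meas = _measurements(["2019-01-09T12:00:00"])
        out = mt.derive_covariates(meas, self._stays(), meas, pd.DataFrame(columns=["stay_id", "charted_time", "ventilation"]), pd.DataFrame(columns=["stay_id", "charted_time", "rass"]))
        assert np.isnan(out.loc[0, "time_to_next_sample_h"])

    def test_time_to_next_matches_bruteforce_scan(self):
        rng = np.random.default_rng(21)
        times = sorted(T("2019-01-07T00:00:00") + pd.Timedelta(minutes=int(m)) for m in rng.choice(10_000, 60, replace=False))
        meas = _measurements(times)
        out = mt.derive_covariates(meas, self._stays(), meas, pd.DataFrame(columns=["stay_id", "charted_time", "ventilation"]), pd.DataFrame(columns=["stay_id", "charted_time", "rass"]))
        for i, t in enumerate(times):
            later = [x for x in times if x > t]
            expect = (min(later) - t).total_seconds() / 3600.0 if later else np.nan
            got = out.loc[i, "time_to_next_sample_h"]
            assert (np.isnan(got) and np.isnan(expect)) or got == pytest.approx(expect)

    def test_state_carry_forward(self):
        vent = pd.DataFrame({
            "stay_id": ["s1", "s1"],
            "charted_time": pd.to_datetime(["2019-01-07T00:00:00", "2019-01-10T00:00:00"]),
            "ventilation": ["invasive", "none"],
        })
        rass = pd.DataFrame({
            "stay_id": ["s1"],
            "charted_time": pd.to_datetime(["2019-01-08T00:00:00"]),
            "rass": [-3],
        })
        meas = _measurements(["2019-01-07T12:00:00", "2019-01-11T00:00:00"])
        out = mt.derive_covariates(meas, self._stays(), meas, vent, rass)
        assert list(out["ventilation"]) == ["invasive", "none"]
        assert pd.isna(out.loc[0, "rass"]) and out.loc[1, "rass"] == -3


def test_window_corrections_are_pure():
    e = _event("insulin", "short", "2019-01-01T08:00:00", "2019-01-01T09:00:00", rate=2)
    assert mt.correct_window(e) == mt.correct_window(dict(e))


def test_build_analysis_table_columns_and_consistency(small_rows):
    """Category labels agree with the continuous fields at the documented bands."""
    from icuglucose.datamodel import (
        ANALYSIS_COLUMNS,
        categorise_carb,
        categorise_dextrose,
        categorise_insulin,
    )

    assert list(small_rows.columns) == ANALYSIS_COLUMNS
    assert list(small_rows["carb_cat"]) == list(categorise_carb(small_rows["carb_rate_g_h"]))
    assert list(small_rows["insulin_cat"]) == list(categorise_insulin(small_rows["insulin_rate_u_h"]))
    assert list(small_rows["dextrose_cat"]) == list(categorise_dextrose(small_rows["dextrose_rate_g_h"]))
    assert small_rows["hour_bin"].between(0, 23).all()
    assert (small_rows["days_since_admission"] >= 0).all()
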