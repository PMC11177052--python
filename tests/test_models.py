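"""Model sequence, LRT bookkeeping, EMM contrasts and diagnostics."""

import warnings

import numpy as np
import pandas as pd
import pytest

from icuglucose import models as md


@pytest.fixture(scope="module")
def ml_fits(small_rows):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return md.fit_model_sequence(small_rows, objectives=("ML",))


def test_fixed_parameter_counts_grow_1_6_16_39(ml_fits):
    assert [ml_fits[m]["ML"].n_fixed_params for m in md.MODEL_SEQUENCE] == [1, 6, 16, 39]


def test_profiled_fitter_agrees_with_statsmodels_mixedlm(small_rows):
    """Independent cross-check of the 1-D profiled fitter against MixedLM.

    Coefficients, variance components and both log-likelihoods must agree to
    optimiser precision on the same design matrix.
    """
    import statsmodels.api as sm

    sub = small_rows[small_rows["stay_id"].isin(small_rows["stay_id"].unique()[:40])]
    X, names = md.build_design(sub, md.MODEL_TERMS["m3"])
    keep = X.any(axis=0)
    X = X[:, keep]
    y = sub["glucose_mmol_l"].to_numpy(float)
    groups = sub["stay_id"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mine = md.fit_model(sub, "m3", reml=False)
        mine_r = md.fit_model(sub, "m3", reml=True)
        sm_ml = sm.MixedLM(y, X, groups=groups).fit(reml=False)
        sm_reml = sm.MixedLM(y, X, groups=groups).fit(reml=True)
    assert mine.fe_params == pytest.approx(np.asarray(sm_ml.fe_params), abs=1e-4)
    assert mine.log_likelihood == pytest.approx(sm_ml.llf, abs=1e-3)
    assert mine.residual_variance == pytest.approx(sm_ml.scale, rel=1e-3)
    assert mine.random_intercept_variance == pytest.approx(
        float(np.asarray(sm_ml.cov_re).ravel()[0]), abs=1e-2
    )
    assert mine_r.log_likelihood == pytest.approx(sm_reml.llf, abs=1e-3)
    assert np.sqrt(np.diag(mine_r.cov_fe)) == pytest.approx(np.asarray(sm_reml.bse_fe), rel=1e-2)


class TestLrt:
    def test_identical_models_give_zero_statistic(self, ml_fits):
        r = md.lrt(ml_fits["m3"]["ML"], ml_fits["m3"]["ML"])
        assert r.chi_square == 0.0 and r.p_value == 1.0

    def test_sequence_dfs_are_5_10_23(self, ml_fits):
        dfs = [
            md.lrt(ml_fits[a]["ML"], ml_fits[b]["ML"]).df
            for a, b in zip(md.MODEL_SEQUENCE[:-1], md.MODEL_SEQUENCE[1:])
        ]
        assert dfs == [5, 10, 23]

    def test_reml_fits_are_rejected(self, small_rows, m4_fits):
        with pytest.raises(ValueError, match="ML"):
            md.lrt(m4_fits["REML"], m4_fits["REML"])

    def test_non_nested_pair_rejected(self, ml_fits):
        with pytest.raises(ValueError, match="nested"):
            md.lrt(ml_fits["m4"]["ML"], ml_fits["m2"]["ML"])


def test_one_patient_input_is_an_error(small_rows):
    one = small_rows[small_rows["stay_id"] == small_rows["stay_id"].iloc[0]]
    with pytest.raises(ValueError, match="2 patients"):
        md.fit_model(one, "m1")


def test_singular_fit_warns_not_fails():
    """No between-patient variance -> warning, usable fit."""
    rng = np.random.default_rng(0)
    rows = pd.DataFrame({
        "stay_id": np.repeat([f"s{i}" for i in range(20)], 30),
        "glucose_mmol_l": rng.normal(8.0, 1.0, 600),  # no patient structure
    })
    with pytest.warns(md.SingularFitWarning):
        fit = md.fit_model(rows, "m1", reml=True)
    assert fit.random_intercept_variance == pytest.approx(0.0, abs=1e-6)
    assert fit.fe_params[0] == pytest.approx(8.0, abs=0.2)


class TestEmm:
    def _toy_fit(self):
        """Small hand-checkable fit: sex + diabetes + hour, known coefficients."""
        fit = md.ModelFit(
            model_id="toy", fit_objective="ML", terms=["sex", "diabetes", "hour"],
            fe_names=["Intercept", "sex[male]", "diabetes[True]"]
            + [f"hour[{h}]" for h in range(1, 24)],
            fe_params=np.concatenate([[6.0, -0.2, 2.0], np.linspace(0, 1, 23)]),
            cov_fe=np.eye(26) * 0.01,
            random_intercept_variance=1.0, residual_variance=2.0,
            log_likelihood=0.0, n_obs=10, n_groups=2,
        )
        return fit

    def test_emm_matches_manual_formula(self):
        """EMM(h) = b0 + hour_h + mean(sex levels) + mean(diabetes levels)."""
        fit = self._toy_fit()
        profile = md.emm_profile(fit)
        hour_eff = np.concatenate([[0.0], np.linspace(0, 1, 23)])
        expect = 6.0 + hour_eff + (-0.2) / 2 + 2.0 / 2
        assert profile.emm == pytest.approx(expect)

    def test_emm_ci_from_contrast_variance(self):
        fit = self._toy_fit()
        table = md.emm_by_hour(fit)
        c = np.zeros(26)
        c[0], c[1], c[2] = 1.0, 0.5, 0.5
        se0 = float(np.sqrt(c @ fit.cov_fe @ c))
        assert table.loc[0, "ci_high"] - table.loc[0, "emm"] == pytest.approx(1.959964 * se0, rel=1e-6)

    def test_flat_truth_gives_flat_profile(self):
        fit = self._toy_fit()
        fit.fe_params = np.concatenate([[6.0, 0.0, 0.0], np.zeros(23)])
        profile = md.emm_profile(fit)
        assert profile.emm == pytest.approx(np.full(24, 6.0))
        assert profile.amplitude == 0.0

    def test_hour_only_model_emm_equals_intercept_plus_hour_effect(self, small_rows):
        """Without other covariates the EMM is exactly the mixed-model hourly mean."""
        rows = small_rows
        X, names = md.build_design(rows, ["hour"])
        y = rows["glucose_mmol_l"].to_numpy(float)
        prof_engine = md._ProfiledLikelihood(y, X, pd.factorize(rows["stay_id"])[0])
        theta, beta, cov, var_re, var_e, ll = prof_engine.fit(reml=False)
        hour_fit = md.ModelFit(
            model_id="hour_only", fit_objective="ML", terms=["hour"], fe_names=names,
            fe_params=beta, cov_fe=cov, random_intercept_variance=var_re,
            residual_variance=var_e, log_likelihood=ll, n_obs=len(y),
            n_groups=rows["stay_id"].nunique(),
        )
        profile = md.emm_profile(hour_fit)
        expect = beta[0] + np.concatenate([[0.0], beta[1:]])
        assert profile.emm == pytest.approx(expect)

    def test_frequency_weighting_differs_from_equal(self, m4_fits, small_rows):
        eq = md.emm_profile(m4_fits["ML"], small_rows, weighting="equal")
        fr = md.emm_profile(m4_fits["ML"], small_rows, weighting="frequency")
        assert not np.allclose(eq.emm, fr.emm)
        # both profiles have identical hour-to-hour shape (contrast differences)
        assert np.diff(eq.emm) == pytest.approx(np.diff(fr.emm), abs=1e-9)

    def test_peak_and_trough_are_argmax_argmin(self, m4_fits, small_rows):
        profile = md.emm_profile(m4_fits["ML"], small_rows)
        assert profile.emm[profile.peak_hour] >= profile.emm.max() - 1e-12
        assert profile.emm[profile.trough_hour] <= profile.emm.min() + 1e-12
        assert profile.amplitude == pytest.approx(profile.emm.max() - profile.emm.min())


def test_cosinor_recovers_exact_sinusoid():
    h = np.arange(24)
    y = 5.0 + 0.7 * np.cos(2 * np.pi * (h - 10.0) / 24.0)
    cs = md.cosinor_summary(y)
    assert cs.mesor == pytest.approx(5.0, abs=1e-9)
    assert cs.amplitude == pytest.approx(0.7, abs=1e-9)
    assert cs.acrophase_h == pytest.approx(10.0, abs=1e-9)
    assert cs.peak_hour == 10 and cs.trough_hour == 22


class TestDiagnostics:
    def test_conditional_residuals_center_and_shape(self, m4_fits, small_rows):
        d = md.diagnostics(m4_fits["REML"], small_rows)
        resid = d["residuals"]["residual"]
        assert abs(resid.mean()) < 0.05
        skew = float(((resid - resid.mean()) ** 3).mean() / resid.std() ** 3)
        assert abs(skew) < 0.2
        assert len(d["residuals"]) == len(small_rows)
        assert list(d["qq"].columns) == ["theoretical", "sample"]

    def test_deterministic(self, m4_fits, small_rows):
        a = md.diagnostics(m4_fits["REML"], small_rows)
        b = md.diagnostics(m4_fits["REML"], small_rows)
        pd.testing.assert_frame_equal(a["residuals"], b["residuals"])
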