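"""GAMM estimation, inference helpers, and cross-model tests.

Heavy Monte-Carlo calibration checks (type-I error at 500 reps, masking
property) live in tests/test_acceptance.py; this file covers structural
correctness and small-sample statistical behaviour.
"""

import numpy as np
import pandas as pd
import pytest

from tests.conftest import NULL_EFFECTS
from thermopose.extraction import window_average
from thermopose.gamm import (
    ThermalResponseGAMM,
    breusch_pagan,
    incidence_weights,
    levene_exclusion,
    likelihood_ratio_test,
)
from thermopose.simulate import SimulationConfig, ar1_noise, simulate_records


def windowed(seed=0, region="eye", **cfg_kw):
    cfg = SimulationConfig(seed=seed, **cfg_kw)
    win = window_average(simulate_records(cfg))
    return win[win["region"] == region].reset_index(drop=True)


@pytest.fixture(scope="module")
def eye_fit():
    model = ThermalResponseGAMM(windowed(seed=5))
    return model, model.fit()


@pytest.fixture(scope="module")
def bill_fit():
    model = ThermalResponseGAMM(windowed(seed=5, region="bill"))
    return model, model.fit()


class TestModelStructure:
    def test_design_dimensions(self, eye_fit):
        model, fit = eye_fit
        # Intercept + treatment + 3 time + 3 difference + 14 indicators
        assert len(fit.params) == 2 + 3 + 3 + 14
        assert set(model.term_slices) >= {"s(time)", "s(time):treatment",
                                          "re(individual)"}

    def test_yaw_model_adds_five_columns(self):
        records = windowed(seed=6)
        base = ThermalResponseGAMM(records)
        yaw = ThermalResponseGAMM(records, include_yaw=True)
        assert len(yaw.exog_names) == len(base.exog_names) + 5

    def test_difference_smooth_zero_for_controls(self, eye_fit):
        model, _ = eye_fit
        control = model.records["treatment"].to_numpy() == "control"
        cols = model.exog[:, model.term_slices["s(time):treatment"]]
        assert np.all(cols[control] == 0.0)

    def test_single_treatment_rejected(self):
        records = windowed(seed=7)
        with pytest.raises(ValueError):
            ThermalResponseGAMM(records[records["treatment"] == "stress"])

    def test_missing_yaw_rows_dropped_for_yaw_model(self):
        records = windowed(seed=8)
        records.loc[records.index[:30], "yaw_deg"] = np.nan
        m = ThermalResponseGAMM(records, include_yaw=True)
        assert len(m.records) == len(records) - 30


class TestFitInvariants:
    def test_rho_in_open_interval(self, eye_fit):
        _, fit = eye_fit
        assert -1.0 < fit.rho < 1.0

    def test_edf_bounds(self, eye_fit):
        _, fit = eye_fit
        for term, k in [("s(time)", 3), ("s(time):treatment", 3)]:
            edf = fit.term_edf(term)
            assert 0.0 < edf <= k + 1e-8

    def test_random_sds_nonnegative(self, eye_fit):
        _, fit = eye_fit
        assert all(sd >= 0.0 for sd in fit.random_sds.values())

    def test_deviance_explained_unit_interval(self, bill_fit):
        _, fit = bill_fit
        assert 0.0 <= fit.deviance_explained <= 1.0

    def test_fittedvalues_residuals_decompose(self, eye_fit):
        model, fit = eye_fit
        y = model.records["temp_max_C"].to_numpy()
        np.testing.assert_allclose(fit.fittedvalues + fit.resid, y, atol=1e-8)

    def test_idempotence_on_own_fitted_values(self, eye_fit):
        # refitting on noiseless fitted values reproduces the coefficients
        model, fit = eye_fit
        rec = model.records.copy()
        rec["temp_max_C"] = fit.fittedvalues
        refit = ThermalResponseGAMM(rec).fit(rho=fit.rho)
        np.testing.assert_allclose(refit.params.to_numpy(),
                                   fit.params.to_numpy(), atol=1e-6)

    def test_fixed_rho_respected(self):
        fit = ThermalResponseGAMM(windowed(seed=9)).fit(rho=0.4)
        assert fit.rho == 0.4

    def test_weights_accepted(self):
        records = windowed(seed=10)
        w = np.ones(len(records))
        fit_w = ThermalResponseGAMM(records, weights=w).fit()
        fit_u = ThermalResponseGAMM(records).fit()
        # unit weights must reproduce the unweighted fit
        np.testing.assert_allclose(fit_w.params.to_numpy(),
                                   fit_u.params.to_numpy(), atol=1e-8)

    def test_summary_contains_key_sections(self, bill_fit):
        _, fit = bill_fit
        s = fit.summary()
        for token in ["Parametric coefficients", "Smooth terms",
                      "Random effect standard deviations", "AR1 rho",
                      "s(time):treatment", "Deviance explained"]:
            assert token in s


class TestSmoothTest:
    def test_zero_coefficients_give_f_zero_p_one(self, eye_fit):
        _, fit = eye_fit
        zeroed = fit.params.copy()
        original = fit.params
        try:
            fit.params = zeroed * 0.0
            t = fit.smooth_test("s(time):treatment")
            assert t.statistic == 0.0 and t.p_value == 1.0
        finally:
            fit.params = original

    def test_strong_effect_detected(self):
        # bill decline of 2.6 degC dwarfs the noise: p < 0.001
        fit = ThermalResponseGAMM(windowed(seed=11, region="bill")).fit()
        t = fit.smooth_test("s(time):treatment")
        assert t.p_value < 0.001

    def test_unknown_term_rejected(self, eye_fit):
        _, fit = eye_fit
        with pytest.raises(KeyError):
            fit.smooth_test("s(nonexistent)")


class TestRhoEstimation:
    def test_whitening_removes_ar1(self):
        # AR1-correct whitening leaves white residuals: |lag-1 r| < 0.05
        rng = np.random.default_rng(0)
        x = ar1_noise(5000, 0.889, 1.0, rng)
        rho = 0.889
        w = (x[1:] - rho * x[:-1]) / np.sqrt(1 - rho**2)
        r = np.corrcoef(w[1:], w[:-1])[0, 1]
        assert abs(r) < 0.05

    def test_frame_level_rho_recovery(self):
        # generator rho 0.889 at frame level; frame-level fit recovers it
        cfg = SimulationConfig(seed=12, **NULL_EFFECTS)
        rec = simulate_records(cfg)
        eye = rec[rec["region"] == "eye"]
        assert len(eye) >= 5000
        fit = ThermalResponseGAMM(eye).fit()
        assert fit.rho == pytest.approx(0.889, abs=0.05)


class TestLikelihoodRatio:
    def test_identical_fits_give_zero(self, eye_fit):
        _, fit = eye_fit
        t = likelihood_ratio_test(fit, fit)
        assert t.statistic == 0.0 and t.p_value == 1.0

    def test_negative_statistic_p_one(self, eye_fit, bill_fit):
        _, a = eye_fit
        _, b = bill_fit
        lo, hi = (a, b) if a.llf_ml > b.llf_ml else (b, a)
        t = likelihood_ratio_test(lo, hi)
        assert t.statistic <= 0.0 and t.p_value == 1.0

    def test_different_row_counts_rejected(self, eye_fit):
        model, fit = eye_fit
        small = ThermalResponseGAMM(model.records.iloc[:-10]).fit()
        with pytest.raises(ValueError):
            likelihood_ratio_test(small, fit)

    def test_random_slope_machinery_detects_heterogeneity(self):
        # With AR1 disabled the base model cannot absorb individual response
        # patterns into an inflated rho, so the LRT must flag the bill-scale
        # slope spread.  (With AR1 free, absorption caps the power in this
        # noise regime; that regime property is measured in the acceptance
        # suite, criterion 6.)
        records = windowed(seed=13, region="bill")
        base = ThermalResponseGAMM(records, ar1=False).fit()
        slope = ThermalResponseGAMM(records, ar1=False, random_slope=True).fit()
        t = likelihood_ratio_test(base, slope)
        assert t.p_value < 0.05


class TestBreuschPagan:
    def test_constant_residuals_statistic_zero(self, eye_fit):
        _, fit = eye_fit
        original = fit.resid
        try:
            fit.resid = np.zeros_like(original)
            t = breusch_pagan(fit, np.linspace(-1, 1, len(original)))
            assert t.statistic == 0.0
        finally:
            fit.resid = original

    def test_power_against_linear_sd_doubling(self, eye_fit):
        # residual SD doubling across the covariate, n=500 -> power >= 0.8
        _, fit = eye_fit
        rng = np.random.default_rng(1)
        n = 500
        rejections = 0
        reps = 40
        original = fit.resid
        try:
            for _ in range(reps):
                x = rng.uniform(0, 1, n)
                resid = rng.normal(0, 1 + x, n)  # SD doubles across x
                fit.resid = resid
                if breusch_pagan(fit, x).p_value < 0.05:
                    rejections += 1
        finally:
            fit.resid = original
        assert rejections / reps >= 0.8

    def test_length_mismatch_rejected(self, eye_fit):
        _, fit = eye_fit
        with pytest.raises(ValueError):
            breusch_pagan(fit, np.arange(3))


class TestLeveneExclusion:
    def test_homogeneous_variances_no_exclusion(self):
        records = windowed(seed=14)
        model = ThermalResponseGAMM(records)
        fit = model.fit()
        excluded, test, refit = levene_exclusion(model, fit)
        # one realization of the null: exclusion should be rare; assert the
        # structural contract (refit identity when nothing excluded)
        if not excluded:
            assert refit is fit

    def test_inflated_individual_excluded(self):
        # one individual with 3x residual SD is flagged in >= 90% of reps
        hits = 0
        reps = 10
        for s in range(reps):
            records = windowed(seed=100 + s)
            bad = "S00"
            rows = records["individual_id"] == bad
            rng = np.random.default_rng(s)
            records.loc[rows, "temp_max_C"] += rng.normal(
                0.0, 2.0 * 0.28, rows.sum())  # 3x the ~0.14 window-level SD
            model = ThermalResponseGAMM(records)
            fit = model.fit()
            excluded, _, refit = levene_exclusion(model, fit)
            if excluded == [bad]:
                hits += 1
                assert bad not in refit.model.individuals
        assert hits >= 9

    def test_at_most_one_exclusion(self):
        records = windowed(seed=15)
        rng = np.random.default_rng(2)
        for bad in ("S00", "S01"):
            rows = records["individual_id"] == bad
            records.loc[rows, "temp_max_C"] += rng.normal(0, 1.0, rows.sum())
        model = ThermalResponseGAMM(records)
        excluded, _, _ = levene_exclusion(model, model.fit())
        assert len(excluded) <= 1

    def test_two_individuals_refuses_with_warning(self):
        records = windowed(seed=16)
        sub = records[records["individual_id"].isin(["S00", "C00"])]
        model = ThermalResponseGAMM(sub)
        fit = model.fit()
        with pytest.warns(UserWarning, match="refusing"):
            excluded, _, _ = levene_exclusion(model, fit)
        assert excluded == []


class TestMarginalMeans:
    def test_recovers_generator_means(self):
        # noiseless-ish bill data: marginal means match generating levels
        records = windowed(seed=17, region="bill", resid_sd_C=0.05,
                           indiv_intercept_sd_C=0.0,
                           indiv_slope_sd_bill_C=0.0)
        fit = ThermalResponseGAMM(records).fit()
        pre, _ = fit.marginal_mean((-210.0, 0.0), "stress")
        post, _ = fit.marginal_mean((60.0, 211.0), "stress")
        assert pre - post == pytest.approx(2.6, abs=0.15)

    def test_control_window_matches_sample_mean(self):
        records = windowed(seed=18, **NULL_EFFECTS)
        fit = ThermalResponseGAMM(records).fit()
        mean, sem = fit.marginal_mean((-210.0, 211.0), "control")
        sample = records.loc[records["treatment"] == "control",
                             "temp_max_C"].mean()
        assert mean == pytest.approx(sample, abs=3 * sem + 0.05)
        assert sem > 0

    def test_empty_window_rejected(self):
        fit = ThermalResponseGAMM(windowed(seed=19)).fit()
        with pytest.raises(ValueError):
            fit.marginal_mean((10_000.0, 10_001.0), "stress")


class TestIncidenceWeights:
    def test_mean_one_and_positive(self, eye_fit):
        _, fit = eye_fit
        yaw = fit.model.records["yaw_deg"].to_numpy()
        w = incidence_weights(fit, yaw)
        assert w.mean() == pytest.approx(1.0)
        assert np.all(w > 0)

    def test_downweights_high_variance_angles(self, eye_fit):
        _, fit = eye_fit
        rng = np.random.default_rng(3)
        n = fit.nobs
        yaw = np.linspace(-80, 60, n)
        original = fit.resid
        try:
            fit.resid = rng.normal(0, 0.1 + 0.02 * np.abs(yaw), n)
            w = incidence_weights(fit, yaw)
        finally:
            fit.resid = original
        assert w[np.abs(yaw) < 10].mean() > w[np.abs(yaw) > 60].mean()
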