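"""Physiology equations, correlation screening and the fitted model forms."""

import numpy as np
import pandas as pd
import pytest

from dielsense.exceptions import ValidationError
from dielsense.models import (
    ExpoLinearModel,
    LinearRateModel,
    PeakRateModel,
    REFERENCE_EXPOLINEAR_PARAMS,
    REFERENCE_MIN_RPCR_COEFS,
    REFERENCE_PEAK_PARAMS,
    REFERENCE_STEM_WP_COEFS,
    StemWaterPotentialModel,
    compute_rwc,
    correlate,
    detect_threshold,
    expolinear_curve,
    invert_expolinear,
    linear_curve,
    multilinear_predict,
    pair_spot_to_sensor,
    peak_curve,
)


class TestRWC:
    def test_full_turgor_is_100(self):
        assert compute_rwc(1.0, 1.0, 0.2) == pytest.approx(100.0)

    def test_oven_dry_is_0(self):
        assert compute_rwc(0.2, 1.0, 0.2) == pytest.approx(0.0)

    def test_hand_example(self):
        assert compute_rwc(0.8, 1.0, 0.2) == pytest.approx(75.0)

    def test_turgid_not_above_dry_rejected(self):
        with pytest.raises(ValidationError):
            compute_rwc(0.5, 0.2, 0.3)


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p, n = correlate(x, 2.0 * x + 1.0)
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            x, y = rng.normal(size=30), rng.normal(size=30)
            r, _, _ = correlate(x, y)
            xm, ym = x - x.mean(), y - y.mean()
            oracle = float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))
            assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            correlate(np.ones(10), np.arange(10.0))

    def test_gaussian_copula_target_correlation(self):
        """Bivariate normal generated at rho = -0.645 is estimated within
        sampling error (the leaf-pressure vs leaf-water-potential figure)."""
        rho = -0.645
        rng = np.random.default_rng(21)
        cov = [[1.0, rho], [rho, 1.0]]
        x, y = rng.multivariate_normal([0, 0], cov, size=3000).T
        r, p, n = correlate(x, y)
        assert r == pytest.approx(rho, abs=3.0 / np.sqrt(n))
        assert p < 0.001

    def test_pairing_by_nearest_quarter_hour(self):
        sensor = pd.Series(
            np.arange(8.0), index=pd.date_range("2018-01-10 10:00", periods=8, freq="15min")
        )
        spots = pd.DataFrame(
            {"timestamp": [pd.Timestamp("2018-01-10 10:20"), pd.Timestamp("2018-01-10 14:00")]}
        )
        paired = pair_spot_to_sensor(spots, sensor)
        assert paired["sensor_value"].iloc[0] == 1.0  # nearest is 10:15
        assert np.isnan(paired["sensor_value"].iloc[1])  # > 30 min away


class TestMultilinear:
    def _exact_data(self, n=40, seed=2):
        rng = np.random.default_rng(seed)
        psi_leaf = rng.uniform(-4.0, -0.5, n)
        gs = rng.uniform(0.0, 350.0, n)
        vpd = rng.uniform(0.0, 4.0, n)
        psi_stem = multilinear_predict(REFERENCE_STEM_WP_COEFS, psi_leaf, gs, vpd)
        return psi_stem, psi_leaf, gs, vpd

    def test_noiseless_recovery_exact(self):
        res = StemWaterPotentialModel(*self._exact_data()).fit()
        for name, value in REFERENCE_STEM_WP_COEFS.items():
            assert res.params[name] == pytest.approx(value, abs=1e-9)
        assert res.rsquared == pytest.approx(1.0, abs=1e-12)

    def test_intercept_at_zero_predictors(self):
        assert multilinear_predict(REFERENCE_STEM_WP_COEFS, 0.0, 0.0, 0.0) == pytest.approx(-0.311)

    def test_noisy_recovery_within_ci(self):
        rng = np.random.default_rng(17)
        psi_stem, psi_leaf, gs, vpd = self._exact_data(n=80, seed=17)
        res = StemWaterPotentialModel(psi_stem + rng.normal(0, 0.24, 80), psi_leaf, gs, vpd).fit()
        ci = res.conf_int()
        for name, value in REFERENCE_STEM_WP_COEFS.items():
            assert ci.loc[name, "lower"] <= value <= ci.loc[name, "upper"]

    def test_zero_weight_predictor_ci_covers_zero(self):
        rng = np.random.default_rng(23)
        n = 80
        psi_leaf = rng.uniform(-4.0, -0.5, n)
        gs = rng.uniform(0.0, 350.0, n)
        vpd = rng.uniform(0.0, 4.0, n)
        psi_stem = -0.3 + 0.9 * psi_leaf + 0.0 * gs + 0.08 * vpd + rng.normal(0, 0.24, n)
        ci = StemWaterPotentialModel(psi_stem, psi_leaf, gs, vpd).fit().conf_int()
        assert ci.loc["gs", "lower"] <= 0.0 <= ci.loc["gs", "upper"]

    def test_collinear_design_rejected_naming_columns(self):
        rng = np.random.default_rng(5)
        psi_leaf = rng.uniform(-4, -1, 30)
        vpd = 2.0 * psi_leaf + 1.0  # exactly collinear with psi_leaf
        gs = rng.uniform(0, 300, 30)
        with pytest.raises(ValidationError, match="collinear"):
            StemWaterPotentialModel(psi_leaf, psi_leaf, gs, vpd)


class TestPeakModel:
    def test_curve_maximum_at_center(self):
        p = REFERENCE_PEAK_PARAMS
        assert peak_curve(p["center"], **p) == pytest.approx(p["amplitude"])
        grid = np.linspace(-4, 0, 401)
        assert peak_curve(grid, **p).max() <= p["amplitude"] + 1e-15

    def test_even_symmetry_about_center(self):
        p = REFERENCE_PEAK_PARAMS
        for d in (0.1, 0.5, 1.3):
            assert peak_curve(p["center"] + d, **p) == pytest.approx(peak_curve(p["center"] - d, **p))

    def test_noiseless_recovery(self):
        x = np.linspace(-3.6, -0.8, 40)
        y = peak_curve(x, **REFERENCE_PEAK_PARAMS)
        res = PeakRateModel(x, y).fit()
        assert res.params["amplitude"] == pytest.approx(0.04, abs=1e-6)
        assert res.params["center"] == pytest.approx(-1.56, abs=1e-6)
        assert res.params["width"] == pytest.approx(0.57, abs=1e-6)
        assert res.argmax == pytest.approx(-1.56, abs=1e-6)
        assert res.peak_value == pytest.approx(0.04, abs=1e-6)

    def test_noisy_recovery_within_ci(self):
        rng = np.random.default_rng(31)
        x = np.linspace(-3.6, -0.8, 40)
        y = peak_curve(x, **REFERENCE_PEAK_PARAMS) + rng.normal(0, 0.01, 40)
        res = PeakRateModel(x, y).fit()
        ci = res.conf_int()
        for name, value in REFERENCE_PEAK_PARAMS.items():
            assert ci.loc[name, "lower"] <= value <= ci.loc[name, "upper"]


class TestLinearModel:
    def test_reference_intercept(self):
        assert linear_curve(0.0, **REFERENCE_MIN_RPCR_COEFS) == pytest.approx(-0.70)

    def test_noiseless_recovery(self):
        x = np.linspace(-3.6, -0.8, 30)
        res = LinearRateModel(x, linear_curve(x, **REFERENCE_MIN_RPCR_COEFS)).fit()
        assert res.params["intercept"] == pytest.approx(-0.70, abs=1e-9)
        assert res.params["slope"] == pytest.approx(0.55, abs=1e-9)


class TestExpoLinear:
    def test_value_at_zero_is_the_constant(self):
        y0 = expolinear_curve(0.0, **REFERENCE_EXPOLINEAR_PARAMS)
        assert y0 == pytest.approx(-0.07, abs=1e-5)  # exponential term ~ 2.9e-7

    def test_noiseless_recovery(self):
        x = np.linspace(-3.6, -0.8, 60)
        y = expolinear_curve(x, **REFERENCE_EXPOLINEAR_PARAMS)
        res = ExpoLinearModel(x, y).fit()
        for name, value in REFERENCE_EXPOLINEAR_PARAMS.items():
            assert res.params[name] == pytest.approx(value, rel=1e-6)
        assert res.rsquared == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery_within_ci(self):
        rng = np.random.default_rng(41)
        x = np.linspace(-3.6, -0.8, 60)
        y = expolinear_curve(x, **REFERENCE_EXPOLINEAR_PARAMS) + rng.normal(0, 0.03, 60)
        res = ExpoLinearModel(x, y).fit()
        ci = res.conf_int()
        for name, value in REFERENCE_EXPOLINEAR_PARAMS.items():
            assert ci.loc[name, "lower"] <= value <= ci.loc[name, "upper"]

    def test_fitted_k1_is_positive(self):
        rng = np.random.default_rng(43)
        x = np.linspace(-3.6, -0.8, 60)
        y = expolinear_curve(x, **REFERENCE_EXPOLINEAR_PARAMS) + rng.normal(0, 0.03, 60)
        assert ExpoLinearModel(x, y).fit().params["k1"] > 0


class TestThreshold:
    def test_reference_parameters_give_minus_2_3(self):
        """The 1% exponential-contribution point of the reference expo-linear
        curve sits at -2.28 MPa, i.e. -2.3 to one decimal."""
        result = detect_threshold(REFERENCE_EXPOLINEAR_PARAMS, fraction=0.01)
        assert result.psi_threshold == pytest.approx(-2.28, abs=0.01)
        assert round(result.psi_threshold, 1) == -2.3

    def test_purely_linear_has_no_threshold(self):
        params = dict(REFERENCE_EXPOLINEAR_PARAMS, k1=0.0)
        result = detect_threshold(params)
        assert result.psi_threshold is None
        assert result.flag == "purely_linear"

    def test_strictly_decreasing_in_fraction(self):
        thresholds = [
            detect_threshold(REFERENCE_EXPOLINEAR_PARAMS, fraction=f).psi_threshold
            for f in (0.005, 0.01, 0.02, 0.04)
        ]
        assert all(a > b for a, b in zip(thresholds, thresholds[1:]))

    def test_continuous_in_fraction(self):
        a = detect_threshold(REFERENCE_EXPOLINEAR_PARAMS, fraction=0.0100).psi_threshold
        b = detect_threshold(REFERENCE_EXPOLINEAR_PARAMS, fraction=0.0101).psi_threshold
        assert abs(a - b) < 0.01


class TestInversion:
    def test_round_trip(self):
        ratio = float(expolinear_curve(-2.0, **REFERENCE_EXPOLINEAR_PARAMS))
        psi, flag = invert_expolinear(ratio, REFERENCE_EXPOLINEAR_PARAMS)
        assert psi == pytest.approx(-2.0, abs=1e-6)
        assert flag == ""

    def test_out_of_range_clamped_and_flagged(self):
        big = float(expolinear_curve(-3.6, **REFERENCE_EXPOLINEAR_PARAMS)) + 1.0
        psi, flag = invert_expolinear(big, REFERENCE_EXPOLINEAR_PARAMS)
        assert psi == -3.6
        assert flag == "out_of_range"
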