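"""Sensor-signal pipeline: ingestion, QC, smoothing, z-scores, rate transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dielsense.exceptions import QCError, ValidationError
from dielsense.signals import (
    QC_NONPOSITIVE,
    QC_OK,
    QC_SPIKE,
    SensorMeta,
    average_rates,
    compute_rgr,
    compute_rpcr,
    load_sensor_csv,
    qc_filter,
    smooth_series,
    standardize,
)
from tests.conftest import make_series


class TestLoad:
    def _write(self, tmp_path, rows):
        path = tmp_path / "sensor.csv"
        path.write_text("timestamp,value\n" + "\n".join(rows))
        return path

    def test_full_day_loads_clean(self, tmp_path):
        index = pd.date_range("2018-01-10", periods=96, freq="15min")
        path = self._write(tmp_path, [f"{t},{30 + i * 0.001}" for i, t in enumerate(index)])
        series = load_sensor_csv(path, SensorMeta(organ="fruit"))
        assert len(series.values) == 96
        assert (series.qc_flags == QC_OK).all()

    def test_nonpositive_value_flagged_and_gapped(self, tmp_path):
        index = pd.date_range("2018-01-10", periods=10, freq="15min")
        rows = [f"{t},{0.0 if i == 4 else 30.0}" for i, t in enumerate(index)]
        series = load_sensor_csv(self._write(tmp_path, rows), SensorMeta(organ="fruit"))
        assert series.qc_flags.iloc[4] == QC_NONPOSITIVE
        assert np.isnan(series.values.iloc[4])

    def test_missing_points_become_explicit_gaps(self, tmp_path):
        index = pd.date_range("2018-01-10", periods=96, freq="15min")
        keep = [t for i, t in enumerate(index) if i not in {10, 20, 30, 40, 50}]
        series = load_sensor_csv(self._write(tmp_path, [f"{t},30.0" for t in keep]), SensorMeta(organ="fruit"))
        assert len(series.values) == 96
        assert int(series.values.isna().sum()) == 5

    def test_offgrid_snap_and_reject(self, tmp_path):
        rows = [
            "2018-01-10 00:00:30,30.0",  # within 90 s -> snapped to 00:00
            "2018-01-10 00:15:00,30.1",
            "2018-01-10 00:33:00,30.2",  # 3 min off -> rejected
        ]
        series = load_sensor_csv(self._write(tmp_path, rows), SensorMeta(organ="fruit"))
        assert series.values.index[0] == pd.Timestamp("2018-01-10 00:00")
        assert len(series.values.dropna()) == 2

    def test_duplicate_timestamps_error(self, tmp_path):
        rows = ["2018-01-10 00:00,30.0", "2018-01-10 00:00:30,30.1"]
        with pytest.raises(ValidationError, match="duplicate"):
            load_sensor_csv(self._write(tmp_path, rows), SensorMeta(organ="fruit"))


class TestQC:
    def test_clean_series_unflagged(self):
        series = make_series(30.0 + 0.01 * np.sin(np.arange(200) / 10.0))
        filtered = qc_filter(series)
        assert filtered.excluded_fraction == 0.0

    def test_single_spike_flagged_exactly(self):
        values = 30.0 + 0.01 * np.sin(np.arange(200) / 10.0)
        values[77] += 50 * 0.001  # ~50x the median 15-min step
        filtered = qc_filter(make_series(values))
        flagged = np.flatnonzero(filtered.qc_flags.to_numpy() == QC_SPIKE)
        assert list(flagged) == [77]

    def test_excess_corruption_rejected(self):
        values = 30.0 + 0.01 * np.sin(np.arange(200) / 10.0)
        bad = np.arange(5, 5 + 12 * 3, 3)  # 12 spikes = 6% of 200 points
        values[bad] += 1.0
        with pytest.raises(QCError, match="%"):
            qc_filter(make_series(values))

    def test_reported_fraction_is_exact_count_ratio(self):
        values = 30.0 + 0.01 * np.sin(np.arange(300) / 10.0)
        values[[50, 150]] += 1.0
        filtered = qc_filter(make_series(values))
        n_flagged = int((filtered.qc_flags != QC_OK).sum())
        assert filtered.excluded_fraction == n_flagged / 300


class TestSmoothing:
    def test_constant_preserved(self):
        series = make_series(np.full(100, 42.0))
        out = smooth_series(series)
        np.testing.assert_allclose(out.values.to_numpy(), 42.0)
        assert out.is_smoothed

    def test_cubic_polynomial_reproduced(self):
        t = np.arange(120, dtype=float)
        poly = 30.0 + 0.01 * t - 2e-4 * t**2 + 1e-6 * t**3
        out = smooth_series(make_series(poly))
        np.testing.assert_allclose(out.values.to_numpy(), poly, rtol=0, atol=1e-9)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(7)
        noise = rng.normal(0.0, 1.0, 500)
        out = smooth_series(make_series(30.0 + noise))
        assert out.values.std() < noise.std()

    def test_short_segment_passes_through_with_flag(self):
        from dielsense.signals import QC_UNSMOOTHED

        values = np.full(10, 5.0)
        out = smooth_series(make_series(values))
        np.testing.assert_allclose(out.values.to_numpy(), values)
        assert (out.qc_flags == QC_UNSMOOTHED).all()


class TestStandardize:
    def test_three_point_example_sample_sd(self):
        """{1,2,3} has sample sd exactly 1, so z = {-1, 0, +1}."""
        z = standardize(make_series([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z.z.to_numpy(), [-1.0, 0.0, 1.0], atol=1e-12)

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(3)
        z = standardize(make_series(30.0 + rng.normal(0, 0.5, 96)))
        assert z.z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        z1 = standardize(make_series(30.0 + rng.normal(0, 0.5, 96)))
        z2 = standardize(z1)
        np.testing.assert_allclose(z2.z.to_numpy(), z1.z.to_numpy(), atol=1e-12)

    def test_flat_series_errors(self):
        with pytest.raises(ValidationError, match="flat"):
            standardize(make_series(np.full(20, 7.0)))


class TestRates:
    def test_constant_rate_zero(self):
        rgr = compute_rgr(make_series(np.full(50, 30.0)))
        np.testing.assert_allclose(rgr.values.to_numpy(), 0.0, atol=1e-15)
        assert len(rgr.values) == 49  # one fewer point than the source

    def test_doubling_gives_ln2(self):
        rgr = compute_rgr(make_series([10.0, 20.0]))
        assert rgr.values.iloc[0] == pytest.approx(np.log(2.0))

    def test_halving_pressure_gives_minus_ln2(self):
        rpcr = compute_rpcr(make_series([100.0, 50.0], organ="leaf"))
        assert rpcr.values.iloc[0] == pytest.approx(-np.log(2.0))

    @given(scale=st.floats(1e-3, 1e3))
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance(self, scale):
        """Unit changes (mm -> um) leave log-difference rates untouched."""
        values = np.array([10.0, 10.5, 10.2, 11.0, 12.5])
        a = compute_rgr(make_series(values)).values.to_numpy()
        b = compute_rgr(make_series(scale * values)).values.to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_exponential_growth_recovered_exactly(self):
        r = 3.2e-4  # per 15-min interval
        t = np.arange(400, dtype=float)
        rgr = compute_rgr(make_series(20.0 * np.exp(r * t)))
        np.testing.assert_allclose(rgr.values.to_numpy(), r, rtol=0, atol=1e-9)

    def test_per_hour_option_scales_by_four(self):
        series = make_series([10.0, 20.0])
        assert compute_rgr(series, per="hour").values.iloc[0] == pytest.approx(4 * np.log(2.0))

    def test_organ_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compute_rpcr(make_series([1.0, 2.0], organ="fruit"))

    def test_nonpositive_interval_becomes_gap(self):
        values = np.array([10.0, np.nan, 12.0, 13.0])
        rgr = compute_rgr(make_series(values))
        assert rgr.values.isna().sum() == 2  # both intervals touching the gap

    def test_average_rates_rejects_mixed_kinds(self):
        rgr = compute_rgr(make_series([10.0, 11.0]))
        rpcr = compute_rpcr(make_series([100.0, 90.0], organ="leaf"))
        with pytest.raises(ValidationError):
            average_rates([rgr, rpcr])
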