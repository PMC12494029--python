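"""z-scoring, rates, rolling-slope classes, periods and lead-lags."""

import numpy as np
import pandas as pd
import pytest

from fawave import dynamics


def _table(values_by_fa, cell="c0", metric="force_nN", dt=10.0):
    rows = []
    for fa, vals in values_by_fa.items():
        for j, v in enumerate(vals):
            rows.append((cell, fa, j, j * dt, v, 1.0 + 0.001 * j, 2.0 + 0.001 * j))
    return pd.DataFrame(rows, columns=dynamics.TRACE_COLUMNS)


class TestZscore:
    def test_pooled_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        df = _table({"a": rng.uniform(1, 5, 30), "b": rng.uniform(2, 9, 30)})
        z = dynamics.zscore_by_cell(df)
        assert z["z_force_nN"].mean() == pytest.approx(0.0, abs=1e-9)
        assert z["z_force_nN"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        df = _table({"a": rng.uniform(1, 5, 20)})
        df2 = df.copy()
        df2["force_nN"] = 3.0 * df2["force_nN"] + 7.0
        z1 = dynamics.zscore_by_cell(df)["z_force_nN"]
        z2 = dynamics.zscore_by_cell(df2)["z_force_nN"]
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    def test_constant_metric_raises_naming_cell(self):
        df = _table({"a": np.ones(10)})
        with pytest.raises(ValueError, match="force_nN.*c0"):
            dynamics.zscore_by_cell(df)

    def test_per_fa_option_standardizes_each_fa(self):
        rng = np.random.default_rng(2)
        df = _table({"a": rng.uniform(0, 1, 15), "b": 10 + rng.uniform(0, 5, 15)})
        z = dynamics.zscore_by_cell(df, per_fa=True)
        for _, g in z.groupby("fa_id"):
            assert g["z_force_nN"].mean() == pytest.approx(0.0, abs=1e-9)


class TestRates:
    def test_linear_series_constant_rate(self):
        dt = 10.0
        m = 0.25  # per frame
        x = m * np.arange(20)
        r = dynamics.rate_of_change(x, dt)
        np.testing.assert_allclose(r, m * 60 / dt)

    def test_constant_series_zero_rate(self):
        np.testing.assert_allclose(dynamics.rate_of_change(np.ones(10), 5.0), 0.0)

    def test_sinusoid_matches_analytic_derivative(self):
        dt, P = 5.0, 300.0
        t = np.arange(0, 1200, dt)
        x = np.sin(2 * np.pi * t / P)
        r = dynamics.rate_of_change(x, dt)
        analytic = (2 * np.pi / P) * np.cos(2 * np.pi * t / P) * 60
        # O(dt^2) interior accuracy
        np.testing.assert_allclose(r[1:-1], analytic[1:-1], atol=60 * (2 * np.pi / P) ** 3 * dt**2)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            dynamics.rate_of_change(np.array([1.0, 2.0]), 1.0)


class TestRollingSlope:
    dt = 10.0

    def _ramp(self, slope_per_min, n=121):
        return slope_per_min * np.arange(n) * self.dt / 60.0

    def test_flat_steady(self):
        assert dynamics.rolling_slope_classify(np.full(121, 2.0), self.dt) == "steady"

    def test_ramp_above_threshold_increasing(self):
        assert dynamics.rolling_slope_classify(self._ramp(0.02), self.dt) == "increasing"

    def test_ramp_below_threshold_steady(self):
        assert dynamics.rolling_slope_classify(self._ramp(0.005), self.dt) == "steady"

    def test_decay_decreasing(self):
        assert dynamics.rolling_slope_classify(self._ramp(-0.05), self.dt) == "decreasing"

    def test_short_trace_raises(self):
        with pytest.raises(ValueError, match="shorter than"):
            dynamics.rolling_slope_classify(np.ones(10), self.dt)


class TestAutocorrPeriod:
    def test_pure_sinusoid_period(self):
        dt, P = 10.0, 300.0
        t = np.arange(0, 2400, dt)
        x = np.sin(2 * np.pi * t / P)
        p = dynamics.autocorr_period(x, dt, max_lag_s=600.0)
        assert p == pytest.approx(P, abs=dt)

    def test_white_noise_false_peak_rate_below_5pct(self):
        rng = np.random.default_rng(7)
        hits = sum(
            dynamics.autocorr_period(rng.standard_normal(241), 10.0, 600.0) is not None
            for _ in range(100)
        )
        assert hits <= 5

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            dynamics.autocorr_period(np.ones(20), 10.0, 600.0)


class TestCrossCorrLag:
    dt = 10.0

    def test_self_correlation_zero_lag(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        res = dynamics.crosscorr_lag(x, x, self.dt)
        assert res.lag_s == 0.0
        assert res.r == pytest.approx(1.0)

    def test_exact_integer_shift(self):
        rng = np.random.default_rng(1)
        x = np.convolve(rng.standard_normal(260), np.ones(5) / 5, mode="valid")
        b = np.roll(x, 2)[4:]  # b delayed by exactly 2 frames
        a = x[4:]
        res = dynamics.crosscorr_lag(a[:200], b[:200], self.dt)
        assert res.lag_s == pytest.approx(2 * self.dt, abs=1e-6)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_fractional_shift_via_interpolation(self):
        # band-limited signal delayed by 3.2 frames via spectral resampling
        dt = self.dt
        n = 400
        rng = np.random.default_rng(5)
        freqs = np.fft.rfftfreq(n, dt)
        spec = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
        spec[freqs > 1 / (6 * dt)] = 0  # band-limit well below Nyquist
        a = np.fft.irfft(spec, n)
        b = np.fft.irfft(spec * np.exp(-2j * np.pi * freqs * 3.2 * dt), n)
        res = dynamics.crosscorr_lag(a[50:350], b[50:350], dt)
        assert res.lag_s == pytest.approx(3.2 * dt, abs=0.3 * dt)

    def test_antisymmetry(self):
        rng = np.random.default_rng(9)
        a = np.convolve(rng.standard_normal(240), np.ones(7) / 7, mode="valid")
        b = np.convolve(rng.standard_normal(240), np.ones(7) / 7, mode="valid")
        r1 = dynamics.crosscorr_lag(a, b, self.dt)
        r2 = dynamics.crosscorr_lag(b, a, self.dt)
        assert r1.lag_s == pytest.approx(-r2.lag_s, abs=0.5 * self.dt)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            dynamics.crosscorr_lag(np.ones(50), np.arange(50.0), self.dt)


class TestEnsemble:
    def test_identical_lag_gives_zero_dispersion(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(6):
            x = np.convolve(rng.standard_normal(140), np.ones(5) / 5, mode="valid")
            rows.append((x[3:120], np.roll(x, 3)[3:120]))
        df_rows = []
        for i, (a, b) in enumerate(rows):
            for j in range(len(a)):
                df_rows.append(("c0", f"fa{i}", j, j * 10.0, a[j], b[j], 0.0))
        df = pd.DataFrame(df_rows, columns=dynamics.TRACE_COLUMNS)
        df["rate_force_nN"] = df["force_nN"]
        df["rate_fak_ratio"] = df["fak_ratio"]
        df["rate_area_um2"] = 0.0
        s = dynamics.ensemble_lag_summary(df, "force:fak", 10.0)
        assert s["mean_lag_s"] == pytest.approx(30.0, abs=1e-6)
        assert s["sd_lag_s"] == pytest.approx(0.0, abs=1e-6)

    def test_too_few_fas_raise(self):
        df = _table({"a": np.arange(30.0)})
        df = dynamics.add_rates(df, 10.0)
        with pytest.raises(ValueError, match="valid lag"):
            dynamics.ensemble_lag_summary(df, "force:fak", 10.0)


class TestProportionIncreasing:
    def _classes(self, labels_and_forces):
        return pd.DataFrame(
            [("c0", f"fa{i}", lab, f) for i, (lab, f) in enumerate(labels_and_forces)],
            columns=["cell_id", "fa_id", "force_class", "mean_force_nN"],
        )

    def test_all_flat_at_zero(self):
        assert dynamics.proportion_increasing(
            self._classes([("steady", 0.0)] * 8)
        ) == 0.0

    def test_all_ramping(self):
        assert dynamics.proportion_increasing(
            self._classes([("increasing", 3.0)] * 8)
        ) == 1.0

    def test_half_ramps_half_flats(self):
        mix = [("increasing", 3.0)] * 4 + [("steady", 0.0)] * 4
        assert dynamics.proportion_increasing(self._classes(mix)) == 0.5
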