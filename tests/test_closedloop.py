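"""Tests for online oscillation detection, filtering and phase prediction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phaseloop import closedloop as cl
from phaseloop import surrogate as sg


def brute_force_ar1(T):
    """Independent oracle: literal evaluation of the lag-1 autoregression
    estimator with its k/(k-1) prefactor."""
    T = np.asarray(T, float)
    k = len(T)
    tbar = T.mean()
    num = sum((T[i] - tbar) * (T[i + 1] - tbar) for i in range(k - 1))
    den = sum((T[i] - tbar) ** 2 for i in range(k))
    return k / (k - 1) * num / den


class TestTestingStage:
    fs = 1000.0

    def _osc(self, f, n=512, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(n) / self.fs
        return np.sin(2 * np.pi * f * t) + rng.normal(0, noise, n)

    def test_white_noise_returns_none(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 512))
        assert cl.testing_stage(x, self.fs) is None

    def test_common_oscillation_detected(self):
        x = np.stack([self._osc(55.0, seed=0), self._osc(55.0, seed=1)])
        f = cl.testing_stage(x, self.fs)
        assert f == pytest.approx(55.0, abs=4.0)

    def test_oscillation_in_one_area_only_rejected(self):
        rng = np.random.default_rng(2)
        x = np.stack([self._osc(55.0), rng.normal(size=512)])
        assert cl.testing_stage(x, self.fs) is None


class TestRecursiveBandpass:
    def test_impulse_envelope_decays_at_pole_radius(self):
        x = np.zeros(3000)
        x[0] = 1.0
        y = cl.recursive_bandpass(x, 55.0, 1000.0)
        # peaks of the ringing decay as sqrt(0.99)^n
        peaks = []
        for i in range(1, len(y) - 1):
            if y[i] > y[i - 1] and y[i] > y[i + 1] and y[i] > 0:
                peaks.append((i, y[i]))
        idx = np.array([p[0] for p in peaks[2:40]])
        val = np.array([p[1] for p in peaks[2:40]])
        slope = np.polyfit(idx, np.log(val), 1)[0]
        assert slope == pytest.approx(math.log(math.sqrt(0.99)), rel=0.05)

    def test_white_noise_output_peaks_at_center_frequency(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200_000)
        y = cl.recursive_bandpass(x, 55.0, 1000.0)
        from phaseloop.network import oscillation_frequency
        assert oscillation_frequency(y, 1000.0, nperseg=4096) == pytest.approx(55.0, abs=2.0)

    def test_tone_at_center_has_maximal_gain(self):
        t = np.arange(5000) / 1000.0
        gains = []
        for f in (35.0, 55.0, 75.0):
            x = np.sin(2 * np.pi * f * t)
            y = cl.recursive_bandpass(x, 55.0, 1000.0)
            gains.append(np.std(y[2000:]))
        assert np.argmax(gains) == 1

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            cl.recursive_bandpass(np.zeros(10), 600.0, 1000.0)


class TestExtractPeriods:
    def test_pure_sinusoid_periods(self):
        t = np.arange(2000) / 1000.0
        x = np.sin(2 * np.pi * 50.0 * t)
        buf = cl.extract_periods(x, 1000.0)
        np.testing.assert_allclose(buf.periods, 20.0, atol=0.05)

    def test_too_few_crossings(self):
        with pytest.raises(ValueError):
            cl.extract_periods(np.sin(np.linspace(0, 2 * np.pi, 30)), 1000.0)


class TestAR1Coefficient:
    def test_alternating_series_matches_oracle_and_is_negative(self):
        T = [10.0, 12.0, 10.0, 12.0, 10.0, 12.0]
        a = cl.ar1_coefficient(T)
        assert a == pytest.approx(brute_force_ar1(T), rel=1e-12)
        assert a < -0.5

    @given(st.lists(st.floats(min_value=5.0, max_value=50.0), min_size=5, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, T):
        if np.var(T) == 0:
            return
        assert cl.ar1_coefficient(T) == pytest.approx(brute_force_ar1(T), rel=1e-9, abs=1e-12)

    def test_iid_series_near_zero(self):
        rng = np.random.default_rng(0)
        T = rng.normal(20.0, 1.0, 2000)
        assert abs(cl.ar1_coefficient(T)) < 3 / math.sqrt(len(T))

    def test_recovers_generating_coefficient(self):
        T, _ = sg.generate_periods(sg.SurrogateSpec(a=0.4, seed=2), 2000)
        assert cl.ar1_coefficient(T) == pytest.approx(0.4, abs=0.05)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            cl.ar1_coefficient([10.0, 10.0, 10.0, 10.0, 10.0])
        with pytest.raises(ValueError):
            cl.ar1_coefficient([10.0, 11.0])


class TestPredictOnset:
    @staticmethod
    def _buffer(T):
        T = np.asarray(T, float)
        tc = np.concatenate([[0.0], np.cumsum(T)])
        return cl.MonitoringBuffer(crossing_times=tc, periods=T, T_mean=float(T.mean()))

    def test_constant_periods_exact_for_any_s(self):
        buf_T = np.full(20, 20.0) + np.concatenate([[1e-9], np.zeros(19)])  # epsilon variance
        buf = self._buffer(buf_T)
        for s in (1, 2, 5):
            cmd = cl.predict_onset(cl.PredictionModel(scheme="ar1", s=s, phi_target=0.25), buf)
            assert cmd.t_on == pytest.approx(buf.t_last + (s + 0.25) * buf.T_mean, rel=1e-6)

    def test_zero_variance_falls_back_to_linear(self):
        buf = self._buffer(np.full(20, 20.0))
        cmd = cl.predict_onset(cl.PredictionModel(scheme="ar1", s=3), buf)
        assert cmd.scheme == "linear"
        assert cmd.t_on == pytest.approx(buf.t_last + 3 * 20.0 + 0.18 * 20.0)

    def test_onset_in_past_rejected(self):
        buf = self._buffer(np.full(20, 20.0))
        with pytest.raises(ValueError):
            cl.predict_onset(cl.PredictionModel(scheme="linear", s=1),
                             buf, current_time=buf.t_last + 100.0)

    def test_one_step_error_ratio_sqrt_one_minus_a_squared(self):
        # AR(1) forecasting theory: for Gaussian residuals the one-step
        # prediction error of the AR(1) scheme is sqrt(1-a^2) times the
        # linear-extrapolation error
        a = 0.6
        T, _ = sg.generate_periods(sg.SurrogateSpec(a=a, sigma=1.0, seed=9), 6000)
        r = cl.prediction_errors(T, k=20, s=1)
        assert r["ratio"] == pytest.approx(math.sqrt(1 - a ** 2), abs=0.05)

    def test_uncorrelated_periods_ratio_near_one(self):
        T, _ = sg.generate_periods(sg.SurrogateSpec(a=0.0, sigma=1.0, seed=4), 4000)
        r = cl.prediction_errors(T, k=20, s=1)
        assert r["ratio"] == pytest.approx(1.0, abs=0.05)

    def test_rule_of_thumb_small_a_negligible_improvement(self):
        T, _ = sg.generate_periods(sg.SurrogateSpec(a=0.25, sigma=1.0, seed=6), 6000)
        r = cl.prediction_errors(T, k=20, s=1)
        assert r["ratio"] > 0.90  # < ~10% improvement when a < 0.3

    def test_dispersion_grows_with_prediction_window(self):
        T, _ = sg.generate_periods(sg.SurrogateSpec(a=0.4, sigma=1.0, seed=8), 4000)
        sds = [cl.prediction_errors(T, k=20, s=s)["sd_linear"] for s in (1, 3, 6)]
        assert sds[0] < sds[1] < sds[2]

    def test_literal_correction_variant_differs(self):
        T, _ = sg.generate_periods(sg.SurrogateSpec(a=0.5, sigma=1.0, seed=3), 200)
        buf = self._buffer(T[:20])
        dev = cl.predict_onset(cl.PredictionModel(scheme="ar1", s=3), buf)
        lit = cl.predict_onset(cl.PredictionModel(scheme="ar1", s=3,
                                                  literal_correction=True), buf)
        assert dev.t_on != lit.t_on
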