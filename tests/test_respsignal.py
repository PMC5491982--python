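"""Filtering, spectral rate estimation, windows, regression and delays."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from breathcam.respsignal import (
    ActivitySchedule,
    BreathSignal,
    DesignError,
    FilterSpec,
    Segment,
    Spectrum,
    WindowedFeatures,
    breathing_frequency,
    design_bandpass,
    dft,
    estimate_breathing_rate,
    fir_filter,
    recovery_regression,
    response_delay,
    windowed_features,
)


def brute_force_fir(b: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Direct double-loop causal convolution (the defining sum)."""
    y = np.zeros(len(x))
    for n in range(len(x)):
        for k in range(len(b)):
            if n - k >= 0:
                y[n] += b[k] * x[n - k]
    return y


def brute_force_dft(x: np.ndarray) -> np.ndarray:
    """Direct O(N^2) evaluation of the defining DFT sum."""
    n = len(x)
    out = np.empty(n, dtype=complex)
    for k in range(n):
        out[k] = sum(x[m] * np.exp(-1j * k * m * 2 * np.pi / n) for m in range(n))
    return out


class TestDesign:
    def test_coefficients_symmetric_linear_phase(self):
        spec = design_bandpass()
        assert np.allclose(spec.b, spec.b[::-1], atol=1e-15)

    def test_dc_gain_small(self):
        spec = design_bandpass(0.05, 1.5, 512, 10.0)
        assert abs(spec.b.sum()) <= 0.1

    def test_band_order_enforced(self):
        with pytest.raises(ValueError):
            design_bandpass(1.5, 0.05)

    def test_too_few_taps_is_design_error(self):
        with pytest.raises(DesignError):
            design_bandpass(0.05, 1.5, taps=16, fs=10.0)


class TestFirFilter:
    def test_identity_tap(self):
        x = BreathSignal(np.array([3.0, -1.0, 2.0]), 10.0)
        spec = FilterSpec(np.array([1.0]), 0.05, 1.5, 10.0)
        assert np.array_equal(fir_filter(x, spec).x, x.x)

    def test_two_tap_average_by_hand(self):
        x = BreathSignal(np.array([1.0, 1.0, 1.0]), 10.0)
        spec = FilterSpec(np.array([0.5, 0.5]), 0.05, 1.5, 10.0)
        assert np.allclose(fir_filter(x, spec).x, [0.5, 1.0, 1.0])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), m=st.integers(1, 9), n=st.integers(2, 40))
    def test_matches_defining_sum(self, seed, m, n):
        rng = np.random.default_rng(seed)
        b = rng.normal(size=m)
        x = rng.normal(size=n)
        spec = FilterSpec(b, 0.05, 1.5, 10.0)
        got = fir_filter(BreathSignal(x, 10.0), spec).x
        assert np.allclose(got, brute_force_fir(b, x), atol=1e-12)


class TestDft:
    def test_constant_signal_closed_form(self):
        spec = dft(BreathSignal(np.full(16, 3.0), 10.0))
        assert spec.y[0] == pytest.approx(48.0)
        assert np.allclose(spec.magnitudes[1:], 0.0, atol=1e-9)

    def test_bin_aligned_cosine_closed_form(self):
        n = 3000
        y = np.cos(2 * np.pi * 75 * np.arange(n) / n)
        spec = dft(BreathSignal(y, 10.0))
        assert spec.magnitudes[75] == pytest.approx(1500.0, abs=1e-6)
        assert spec.magnitudes[n - 75] == pytest.approx(1500.0, abs=1e-6)
        other = np.delete(spec.magnitudes, [75, n - 75])
        assert other.max() < 1e-6

    def test_matches_defining_sum(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=64)
        got = dft(BreathSignal(x, 10.0)).y
        assert np.max(np.abs(got - brute_force_dft(x))) <= 1e-9

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000), n=st.integers(4, 64))
    def test_conjugate_symmetry_for_real_input(self, seed, n):
        x = np.random.default_rng(seed).normal(size=n)
        y = dft(BreathSignal(x, 10.0)).y
        k = np.arange(1, n)
        assert np.max(np.abs(y[k] - np.conj(y[n - k]))) <= 1e-9

    def test_inverse_reconstruction(self):
        x = np.random.default_rng(2).normal(size=50)
        y = dft(BreathSignal(x, 10.0)).y
        n = len(x)
        recon = np.array(
            [np.sum(y * np.exp(2j * np.pi * np.arange(n) * m / n)) / n for m in range(n)]
        )
        assert np.max(np.abs(recon - x)) <= 1e-9


class TestBreathingFrequency:
    def test_bin_to_frequency_mapping(self):
        n = 3000
        y = np.sin(2 * np.pi * 75 * np.arange(n) / n)
        f_hz, f_bpm, k = breathing_frequency(dft(BreathSignal(y, 10.0)))
        assert (f_hz, f_bpm, k) == (pytest.approx(0.25), pytest.approx(15.0), 75)

    def test_out_of_band_dominant_component_ignored(self):
        n = 1000
        t = np.arange(n) / 10.0
        y = 5.0 * np.sin(2 * np.pi * 2.0 * t) + 1.0 * np.sin(2 * np.pi * 0.3 * t)
        f_hz, _, _ = breathing_frequency(dft(BreathSignal(y, 10.0)), 0.05, 1.5)
        assert f_hz == pytest.approx(0.3, abs=0.011)

    def test_resolution_of_reference_record(self):
        sig = BreathSignal(np.ones(3000), 10.0)
        assert round(sig.resolution_hz, 4) == 0.0033
        assert round(sig.resolution_bpm, 1) == 0.2

    def test_empty_band_rejected(self):
        spec = Spectrum(np.ones(4, dtype=complex), 10.0)
        with pytest.raises(ValueError, match="band"):
            breathing_frequency(spec, 0.01, 0.02)


class TestWindowedFeatures:
    def test_constant_series_window_means(self):
        feats = windowed_features(BreathSignal(np.full(600, 27.3), 10.0), 60.0)
        assert np.allclose(feats.means, 27.3, atol=1e-12)

    def test_window_count(self):
        t = np.arange(3000) / 10.0
        x = np.sin(2 * np.pi * 0.25 * t)
        feats = windowed_features(BreathSignal(x, 10.0), 60.0)
        assert feats.n_windows == 5

    def test_frequency_step_tracked_within_one_window_bin(self):
        fs, half = 10.0, 1800
        t1 = np.arange(half) / fs
        x = np.concatenate(
            [np.sin(2 * np.pi * 0.25 * t1), np.sin(2 * np.pi * (1 / 3) * t1)]
        )  # 15 bpm then 20 bpm
        feats = windowed_features(BreathSignal(x, fs), 60.0)
        assert np.all(np.abs(feats.freqs_bpm[:2] - 15.0) <= 1.0)
        assert np.all(np.abs(feats.freqs_bpm[-2:] - 20.0) <= 1.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="window"):
            windowed_features(BreathSignal(np.ones(30), 10.0), 60.0)


def _line_features(slope_per_min, intercept, n=7, spacing_s=60.0, noise=None, rng=None):
    times = (np.arange(n) + 0.5) * spacing_s
    values = intercept + slope_per_min * times / 60.0
    if noise is not None:
        values = values + rng.normal(0, noise, n)
    return WindowedFeatures(spacing_s, times, values, values)


class TestRecoveryRegression:
    def test_noiseless_temperature_line(self):
        feats = _line_features(-0.16, 30.0)
        r = recovery_regression(feats, (0.0, 420.0), "mean")
        assert r.slope_per_min == pytest.approx(-0.16, abs=1e-9)
        assert r.s_percent == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_frequency_line(self):
        feats = _line_features(-0.72, 20.0)
        r = recovery_regression(feats, (0.0, 420.0), "frequency")
        assert r.slope_per_min == pytest.approx(-0.72, abs=1e-9)
        assert r.s_percent == pytest.approx(0.0, abs=1e-12)

    def test_noisy_slope_recovered_on_average(self):
        rng = np.random.default_rng(33)
        slopes = [
            recovery_regression(
                _line_features(-0.16, 30.0, noise=0.05, rng=rng), (0.0, 420.0)
            ).slope_per_min
            for _ in range(50)
        ]
        assert abs(np.mean(slopes) - (-0.16)) / 0.16 <= 0.05

    def test_too_few_windows_rejected(self):
        feats = _line_features(-0.1, 30.0, n=2)
        with pytest.raises(ValueError, match="three"):
            recovery_regression(feats, (0.0, 420.0))


def _two_segment_schedule(length_s=600.0):
    return ActivitySchedule(
        (Segment(0.0, length_s, "load"), Segment(length_s, 2 * length_s, "rest"))
    )


class TestResponseDelay:
    def test_step_at_90s_recovered_exactly(self):
        fs = 1.0
        x = np.zeros(1200)
        x[690:] = 10.0
        x += 0.001 * np.sin(2 * np.pi * 0.25 * np.arange(1200) / fs)  # carrier
        feats = windowed_features(BreathSignal(x, fs), 60.0)
        delays = response_delay(feats, _two_segment_schedule(), feature="mean")
        assert len(delays) == 1
        assert delays[0].delay_s == pytest.approx(90.0, abs=1e-6)
        assert not delays[0].censored

    def test_constant_feature_censored(self):
        times = (np.arange(20) + 0.5) * 60.0
        vals = np.full(20, 5.0)
        feats = WindowedFeatures(60.0, times, vals, vals)
        delays = response_delay(feats, _two_segment_schedule())
        assert delays[0].censored and delays[0].delay_s == 600.0

    def test_exponential_halfway_crossing_near_ln2_tau(self):
        tau = 120.0
        times = (np.arange(20) + 0.5) * 60.0
        vals = np.where(
            times < 600.0, 1.0, 2.0 - np.exp(-(times - 600.0) / tau)
        )
        feats = WindowedFeatures(60.0, times, vals, vals)
        delays = response_delay(feats, _two_segment_schedule())
        assert abs(delays[0].delay_s - np.log(2) * tau) <= 60.0

    def test_crossing_fraction_validated(self):
        feats = _line_features(-0.1, 30.0, n=20)
        with pytest.raises(ValueError, match="crossing"):
            response_delay(feats, _two_segment_schedule(), crossing=1.5)


class TestSchedule:
    def test_protocol_shape(self):
        sched = ActivitySchedule.exercise_protocol()
        assert sched.total_s == 2400.0
        assert [s.label for s in sched.segments] == ["load", "rest", "load", "rest"]

    def test_gap_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            ActivitySchedule((Segment(0, 10, "load"), Segment(20, 30, "rest")))


def test_filtering_removes_dc_component():
    rng = np.random.default_rng(5)
    x = 30.0 + rng.normal(0, 0.1, 3000)
    spec = design_bandpass(0.05, 1.5, 512, 10.0)
    y = fir_filter(BreathSignal(x, 10.0), spec).x
    # steady-state portion: transient of length M skipped
    assert abs(np.mean(y[512:])) <= 0.1 * abs(np.mean(x))


def test_estimate_breathing_rate_on_noisy_sinusoid():
    rng = np.random.default_rng(10)
    t = np.arange(3000) / 10.0
    x = 30.0 + 0.05 * t / 60.0 + 1.5 * np.sin(2 * np.pi * 0.27 * t)
    x += rng.normal(0, 0.1, 3000)
    f_hz, f_bpm, _ = estimate_breathing_rate(BreathSignal(x, 10.0))
    assert abs(f_hz - 0.27) <= 10.0 / 3000.0
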