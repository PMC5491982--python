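"""Change-map ROI detection, tracking, and region statistics."""

import numpy as np
import pytest

import breathcam as bc
from breathcam.thermal_roi import (
    DetectionError,
    change_map,
    detect_initial_roi,
    flat_field_stats,
    mean_temperature,
    range_fraction,
    roi_series,
    update_roi,
)
from breathcam.types import ROI


class TestChangeMap:
    def test_identical_frames_give_zero_map(self):
        stack = np.full((5, 8, 9), 26.0)
        assert np.all(change_map(stack) == 0)

    def test_single_alternating_pixel(self):
        stack = np.full((6, 10, 10), 26.0)
        stack[1::2, 4, 7] = 28.0
        cmap = change_map(stack, smoothing_radius=0)
        assert cmap[4, 7] == pytest.approx(2.0)
        cmap[4, 7] = 0
        assert np.all(cmap == 0)

    def test_matches_per_pixel_scan_oracle(self):
        rng = np.random.default_rng(3)
        stack = rng.normal(27, 1, (12, 6, 7))
        cmap = change_map(stack, smoothing_radius=0)
        oracle = np.empty((6, 7))
        for r in range(6):
            for c in range(7):
                oracle[r, c] = stack[:, r, c].max() - stack[:, r, c].min()
        assert np.array_equal(cmap, oracle)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="two"):
            change_map(np.zeros((1, 4, 4)))


def _oscillating_stack(rects, shape=(30, 40), n=20, amplitude=2.0):
    stack = np.full((n,) + shape, 26.0)
    for rect in rects:
        stack[1::2, rect.slices[0], rect.slices[1]] += amplitude
    return stack


class TestDetectInitial:
    def test_single_patch_recovered(self):
        true = ROI(10, 12, 18, 24)
        stack = _oscillating_stack([true])
        params = bc.RoiTrackParams(smoothing_radius=0)
        assert detect_initial_roi(stack, params).iou(true) >= 0.5

    def test_static_scene_raises(self):
        with pytest.raises(DetectionError):
            detect_initial_roi(np.full((10, 20, 20), 26.0), bc.RoiTrackParams())

    def test_larger_of_two_patches_wins(self):
        small, big = ROI(3, 3, 7, 7), ROI(15, 20, 24, 32)
        stack = _oscillating_stack([small, big])
        params = bc.RoiTrackParams(smoothing_radius=0, change_quantile=0.8)
        assert detect_initial_roi(stack, params) == big


class TestUpdateRoi:
    def test_static_window_falls_back_to_previous(self):
        prev = ROI(5, 5, 9, 9)
        window = np.full((20, 20, 20), 26.0)
        roi, fell_back = update_roi(prev, window, bc.RoiTrackParams())
        assert roi == prev and fell_back

    def test_nearest_component_to_previous_wins(self):
        a, b = ROI(3, 3, 7, 7), ROI(20, 24, 24, 30)
        stack = _oscillating_stack([a, b])
        params = bc.RoiTrackParams(smoothing_radius=0, change_quantile=0.8)
        roi, fell_back = update_roi(ROI(4, 4, 8, 8), stack, params)
        assert roi == a and not fell_back

    def test_drift_tracked_better_than_fixed_roi(self, drift_run):
        params, truth, temps, trace = drift_run
        ious = np.array(
            [r.iou(t) for r, t in zip(trace.rois, truth.per_frame_mouth_roi)]
        )
        end_fixed_iou = trace.rois[0].iou(truth.per_frame_mouth_roi[-1])
        assert ious.mean() >= 0.5
        assert ious.mean() > end_fixed_iou

    def test_moving_roi_range_exceeds_fixed(self, drift_run):
        params, truth, temps, trace = drift_run
        fixed = roi_series(temps, trace.rois[0])
        assert np.ptp(trace.mean_temp) >= np.ptp(fixed)

    def test_zero_drift_roi_centre_stays_within_one_pixel(self, static_noise_free_run):
        params, truth, temps = static_noise_free_run
        trace = bc.track_roi(temps, params.fs, bc.RoiTrackParams(smoothing_radius=0))
        r0, c0 = trace.rois[0].center
        for roi in trace.rois:
            r, c = roi.center
            assert abs(r - r0) <= 1.0 and abs(c - c0) <= 1.0


def test_tracked_series_reproduces_truth_amplitude(static_noise_free_run):
    """Noise-free tracked mean temperature matches the ground-truth
    breathing sinusoid with <= 10% relative amplitude error."""
    params, truth, temps = static_noise_free_run
    # noise-free data: a tight change threshold isolates the breathing patch
    track = bc.RoiTrackParams(smoothing_radius=0, change_quantile=0.99)
    trace = bc.track_roi(temps, params.fs, track)
    true_amp = np.ptp(truth.per_frame_mean_mouth_temp)
    got_amp = np.ptp(trace.mean_temp)
    assert abs(got_amp - true_amp) / true_amp <= 0.10


class TestRegionStatistics:
    def test_mean_temperature_values(self):
        frame = np.full((6, 6), 26.5)
        assert mean_temperature(frame, ROI(1, 1, 4, 4)) == pytest.approx(26.5)
        frame2 = np.array([[26.0, 27.0], [28.0, 29.0]])
        assert mean_temperature(frame2, ROI(0, 0, 2, 2)) == pytest.approx(27.5)

    def test_mean_temperature_matches_sum_oracle(self):
        rng = np.random.default_rng(9)
        frame = rng.normal(27, 2, (15, 17))
        roi = ROI(2, 3, 11, 16)
        patch = frame[2:11, 3:16]
        assert mean_temperature(frame, roi) == pytest.approx(
            patch.sum() / patch.size, abs=1e-12
        )

    def test_range_fraction_extremes_and_oracle(self):
        frame = np.full((8, 8), 27.0)
        assert range_fraction(frame, ROI(0, 0, 8, 8), 26.0, 28.0) == 100.0
        assert range_fraction(frame, ROI(0, 0, 8, 8), 30.0, 31.0) == 0.0
        rng = np.random.default_rng(4)
        rand = rng.normal(27, 1, (10, 10))
        got = range_fraction(rand, ROI(1, 1, 9, 9), 26.0, 28.0)
        patch = rand[1:9, 1:9]
        count = sum(
            1
            for r in range(8)
            for c in range(8)
            if 26.0 <= patch[r, c] <= 28.0
        )
        assert got == pytest.approx(100.0 * count / 64)

    def test_range_fraction_bad_band_rejected(self):
        with pytest.raises(ValueError, match="t_low"):
            range_fraction(np.zeros((4, 4)), ROI(0, 0, 2, 2), 28.0, 26.0)

    def test_flat_field_stats(self):
        const = np.full((5, 5), 26.0)
        mean, std, lo, hi = flat_field_stats(const)
        assert (mean, std, lo, hi) == (26.0, 0.0, 26.0, 26.0)
        rng = np.random.default_rng(12)
        flat = rng.normal(26.0, 0.1, (100, 100))
        _, std, _, _ = flat_field_stats(flat)
        assert 0.09 <= std <= 0.11
        outlier = np.full((4, 4), 26.0)
        outlier[0, 0] = 30.0
        mean, *_ = flat_field_stats(outlier)
        assert mean == pytest.approx((26.0 * 15 + 30.0) / 16)


def test_range_fraction_precision_on_stationary_scene():
    """24 frames of a thermally stable scene sampled every 5 s: the in-band
    pixel percentage varies by less than 7% of its mean."""
    rng = np.random.default_rng(21)
    roi = ROI(2, 2, 30, 30)
    fractions = [
        range_fraction(rng.normal(27.0, 0.3, (32, 32)), roi, 26.0, 28.0)
        for _ in range(24)
    ]
    fractions = np.array(fractions)
    assert fractions.std() / fractions.mean() <= 0.07
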