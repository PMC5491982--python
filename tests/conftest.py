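"""Shared fixtures: a trained OCR model and calibrated synthetic runs.

The classifier and the heavier simulated sequences are session-scoped —
they are deterministic, so sharing them across tests changes nothing but
run time.
"""

from __future__ import annotations

import numpy as np
import pytest

import breathcam as bc
from breathcam.calibration import BarLayout, grey_to_temperature, read_calibration_bar
from breathcam.pipeline import train_default_classifier
from breathcam.synthgen import drift_path

FRAME_SHAPE = (64, 112)  # small frame: 14-row bar + 50x112 scene


@pytest.fixture(scope="session")
def ocr_model():
    return train_default_classifier(seed=0)


@pytest.fixture(scope="session")
def layout():
    return BarLayout.default(FRAME_SHAPE)


@pytest.fixture(scope="session")
def calibrate_stack(ocr_model, layout):
    """Callable turning simulated thermal frames into a temperature stack."""

    def _go(frames):
        cache = {}
        out = []
        for f in frames:
            key = f.grey[layout.bar_box.slices].tobytes()
            scale = cache.get(key)
            if scale is None:
                scale = read_calibration_bar(f.grey, layout, ocr_model, frame_index=f.index)
                cache[key] = scale
            out.append(
                grey_to_temperature(f.grey[layout.height :, :], scale).astype(np.float32)
            )
        return np.stack(out)

    return _go


@pytest.fixture(scope="session")
def drift_run(calibrate_stack):
    """30 s sequence with sinusoidal head drift (peak speed ~1 px/frame)."""
    center = (0.65 * (FRAME_SHAPE[0] - 14), FRAME_SHAPE[1] / 2)
    path = drift_path(center, 300, 10.0, amplitude_px=(0.0, 20.0), freq_hz=0.075)
    params = bc.SceneParams(
        frame_shape=FRAME_SHAPE, duration=30.0, seed=11, mouth_center_path=path
    )
    frames, truth = bc.simulate_thermal_sequence(params)
    temps = calibrate_stack(frames)
    track = bc.RoiTrackParams(history_sec=2.0, smoothing_radius=0)
    trace = bc.track_roi(temps, params.fs, track)
    return params, truth, temps, trace


@pytest.fixture(scope="session")
def static_noise_free_run(calibrate_stack):
    """30 s noise-free sequence, static head, breathing at 0.25 Hz."""
    params = bc.SceneParams(
        frame_shape=FRAME_SHAPE, duration=30.0, seed=5, noise_std=0.0,
        temp_drift_rate=0.0,
    )
    frames, truth = bc.simulate_thermal_sequence(params)
    temps = calibrate_stack(frames)
    return params, truth, temps
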