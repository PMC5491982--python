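"""Chest-motion breathing series from depth-matrix sequences.

The depth sensor delivers per-pixel distances in metres; breathing is read
off as the mean distance of a fixed, user-selected chest region over time.
Pixels outside the sensor's valid range (or non-finite, as real
time-of-flight sensors produce at dropouts) are excluded from the mean and
counted.
"""

from __future__ import annotations

import numpy as np

from .respsignal import BreathSignal
from .synthgen import DEPTH_RANGE, DepthFrame
from .types import ROI

__all__ = ["extract_depth_series", "mean_distance"]


def _patch(frame, roi: ROI) -> np.ndarray:
    values = np.asarray(getattr(frame, "values", frame), dtype=float)
    if not roi.within(values.shape):
        raise ValueError(f"{roi} outside depth frame {values.shape}")
    return values[roi.slices]


def mean_distance(
    frame,
    roi: ROI,
    valid_range: tuple[float, float] = DEPTH_RANGE,
) -> tuple[float, int]:
    """Mean distance (m) over valid region pixels, plus the invalid count.

    A pixel is invalid when non-finite or outside ``valid_range``.
    """
    patch = _patch(frame, roi)
    valid = np.isfinite(patch) & (patch >= valid_range[0]) & (patch <= valid_range[1])
    n_invalid = int(patch.size - np.count_nonzero(valid))
    if not valid.any():
        raise ValueError(f"all {patch.size} region pixels invalid")
    return float(patch[valid].mean()), n_invalid


def extract_depth_series(
    frames,
    roi: ROI,
    fs: float,
    valid_range: tuple[float, float] = DEPTH_RANGE,
) -> tuple[BreathSignal, np.ndarray]:
    """Per-frame mean chest distance as a uniformly sampled breathing signal.

    Returns the signal plus the per-frame invalid-pixel counts.  Frame-level
    failures (a fully invalid region) propagate with the frame index.
    """
    if len(frames) == 0:
        raise ValueError("empty depth sequence")
    means = np.empty(len(frames))
    invalid = np.empty(len(frames), dtype=int)
    for i, frame in enumerate(frames):
        try:
            means[i], invalid[i] = mean_distance(frame, roi, valid_range)
        except ValueError as exc:
            raise ValueError(f"frame {i}: {exc}") from exc
    return BreathSignal(x=means, fs=fs), invalid
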