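"""Adaptive mouth-region detection and tracking in calibrated thermal video.

Breathing shows up as the image region with the largest temperature changes
over a short history window (exhaled air warms the mouth/nostril area
periodically).  The tracker thresholds a per-pixel peak-to-peak change map
at a high quantile, keeps connected components of plausible area, and
follows the component nearest the previous region — tolerating slow head
movement without any facial-landmark machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import (
    label,
    maximum_filter1d,
    minimum_filter1d,
    uniform_filter,
)

from .types import ROI

__all__ = [
    "DetectionError",
    "RoiTrace",
    "RoiTrackParams",
    "change_map",
    "detect_initial_roi",
    "flat_field_stats",
    "mean_temperature",
    "range_fraction",
    "roi_series",
    "track_roi",
    "update_roi",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


class DetectionError(RuntimeError):
    """No mouth-like region of temperature change could be found."""


@dataclass(frozen=True)
class RoiTrackParams:
    """Tuning of the change-based ROI detector/tracker.

    history_sec
        Length of the trailing window over which temperature changes are
        accumulated, 1-8 s.
    init_frames
        Number of initial frames used for the first detection; defaults to
        one history window.
    change_quantile
        Change-map quantile used as detection threshold.
    min_area / max_area
        Component-area bounds in pixels; ``max_area`` defaults to a quarter
        of the frame.
    smoothing_radius
        Box-smoothing radius applied to the change map (0 disables it).
    """

    history_sec: float = 4.0
    init_frames: int | None = None
    change_quantile: float = 0.95
    min_area: int = 9
    max_area: int | None = None
    smoothing_radius: int = 1

    def __post_init__(self) -> None:
        if not 1.0 <= self.history_sec <= 8.0:
            raise ValueError("history_sec must lie in [1, 8] s")
        if not 0.0 < self.change_quantile < 1.0:
            raise ValueError("change_quantile must lie in (0, 1)")
        if self.min_area < 1 or self.smoothing_radius < 0:
            raise ValueError("min_area must be >= 1 and smoothing_radius >= 0")

    def window_frames(self, fs: float) -> int:
        return max(2, int(round(self.history_sec * fs)))

    def resolved_max_area(self, frame_shape: tuple[int, int]) -> int:
        return self.max_area or (frame_shape[0] * frame_shape[1]) // 4


@dataclass
class RoiTrace:
    """Per-frame tracking result: region, mean temperature, area, fallback."""

    rois: list[ROI]
    mean_temp: np.ndarray
    area: np.ndarray
    fallback: np.ndarray  # bool; True where the previous ROI was kept

    def __len__(self) -> int:
        return len(self.rois)

    @property
    def fallback_rate(self) -> float:
        return float(np.mean(self.fallback))


def change_map(temp_frames: np.ndarray, smoothing_radius: int = 0) -> np.ndarray:
    """Per-pixel peak-to-peak temperature change over a frame window.

    ``temp_frames`` is a (k, rows, cols) stack; the result is max - min per
    pixel, optionally box-smoothed.  Non-negative by construction.
    """
    stack = np.asarray(temp_frames, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a stack of at least two equally shaped frames")
    cmap = stack.max(axis=0) - stack.min(axis=0)
    if smoothing_radius > 0:
        cmap = uniform_filter(cmap, size=2 * smoothing_radius + 1, mode="nearest")
    return cmap


def _components(cmap: np.ndarray, params: RoiTrackParams):
    """Qualifying connected components of the thresholded change map.

    Yields (ROI bounding box, area, centroid) for 8-connected components
    whose area lies within the configured bounds.
    """
    thr = float(np.quantile(cmap, params.change_quantile))
    mask = cmap >= thr if thr > 0 else cmap > 0
    if not mask.any():
        return []
    labels, n = label(mask, structure=_EIGHT_CONNECTED)
    max_area = params.resolved_max_area(cmap.shape)
    counts = np.bincount(labels.ravel())
    out = []
    for lab in range(1, n + 1):
        area = int(counts[lab])
        if not params.min_area <= area <= max_area:
            continue
        rr, cc = np.nonzero(labels == lab)
        roi = ROI(int(rr.min()), int(cc.min()), int(rr.max()) + 1, int(cc.max()) + 1)
        out.append((roi, area, (float(rr.mean()), float(cc.mean()))))
    return out


def detect_initial_roi(temp_frames: np.ndarray, params: RoiTrackParams) -> ROI:
    """Detect the mouth region from the initial frames.

    Largest qualifying component of the thresholded, smoothed change map;
    ties resolve to the lower (r0, c0) corner.
    """
    stack = np.asarray(temp_frames, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need at least two initial frames")
    cmap = change_map(stack, params.smoothing_radius)
    comps = _components(cmap, params)
    if not comps:
        raise DetectionError("no connected change component within area bounds")
    comps.sort(key=lambda c: (-c[1], c[0].r0, c[0].c0))
    return comps[0][0]


def update_roi(
    prev: ROI, temp_frames: np.ndarray, params: RoiTrackParams
) -> tuple[ROI, bool]:
    """One tracking step over the trailing history window.

    Returns (roi, fell_back): among qualifying components the one whose
    centroid is nearest the previous centre wins (ties: larger area, then
    lower (r0, c0)); when nothing qualifies the previous ROI is kept and
    flagged.
    """
    cmap = change_map(np.asarray(temp_frames, dtype=float), params.smoothing_radius)
    return _choose_near(prev, cmap, params)


def _choose_near(prev: ROI, cmap: np.ndarray, params: RoiTrackParams) -> tuple[ROI, bool]:
    comps = _components(cmap, params)
    if not comps:
        return prev, True
    pr, pc = prev.center
    comps.sort(
        key=lambda c: (
            (c[2][0] - pr) ** 2 + (c[2][1] - pc) ** 2,
            -c[1],
            c[0].r0,
            c[0].c0,
        )
    )
    return comps[0][0], False


def track_roi(
    temp_frames: np.ndarray,
    fs: float,
    params: RoiTrackParams | None = None,
    init_roi: ROI | None = None,
) -> RoiTrace:
    """Track the mouth region through a whole calibrated sequence.

    The first ``init_frames`` frames share the initial detection (or the
    supplied ``init_roi``); every later frame re-detects over its trailing
    history window.  Rolling per-pixel extrema are computed in one pass so
    whole records track in seconds.
    """
    params = params or RoiTrackParams()
    stack = np.asarray(temp_frames, dtype=np.float32)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a (frames, rows, cols) stack with >= 2 frames")
    n = stack.shape[0]
    w = params.window_frames(fs)
    init_n = params.init_frames or w
    init_n = min(max(init_n, 2), n)
    if init_roi is None:
        init_roi = detect_initial_roi(stack[:init_n], params)

    rois: list[ROI] = [init_roi] * min(init_n, n)
    fallback = np.zeros(n, dtype=bool)
    if n > init_n:
        # trailing-window rolling extrema: origin (w-1)//2 aligns the window
        # to [i-w+1, i]; 'nearest' padding truncates it correctly at the start
        org = (w - 1) // 2
        mx = maximum_filter1d(stack, size=w, axis=0, mode="nearest", origin=org)
        mn = minimum_filter1d(stack, size=w, axis=0, mode="nearest", origin=org)
        prev = init_roi
        size = 2 * params.smoothing_radius + 1
        for i in range(init_n, n):
            cmap = (mx[i] - mn[i]).astype(float)
            if params.smoothing_radius > 0:
                cmap = uniform_filter(cmap, size=size, mode="nearest")
            roi, fell = _choose_near(prev, cmap, params)
            rois.append(roi)
            fallback[i] = fell
            prev = roi

    mean_t = np.array([float(stack[i][r.slices].mean()) for i, r in enumerate(rois)])
    area = np.array([r.area for r in rois])
    return RoiTrace(rois=rois, mean_temp=mean_t, area=area, fallback=fallback)


def mean_temperature(frame: np.ndarray, roi: ROI) -> float:
    """Arithmetic mean temperature over the region."""
    frame = np.asarray(frame, dtype=float)
    if not roi.within(frame.shape):
        raise ValueError(f"{roi} outside frame {frame.shape}")
    return float(frame[roi.slices].mean())


def roi_series(temp_frames: np.ndarray, roi: ROI) -> np.ndarray:
    """Per-frame mean temperature of a fixed region over a stack."""
    stack = np.asarray(temp_frames, dtype=float)
    if not roi.within(stack.shape[1:]):
        raise ValueError(f"{roi} outside frames {stack.shape[1:]}")
    return stack[:, roi.slices[0], roi.slices[1]].mean(axis=(1, 2))


def range_fraction(frame: np.ndarray, roi: ROI, t_low: float, t_high: float) -> float:
    """Percentage of region pixels with temperature in [t_low, t_high].

    Used for camera-precision assessment: on a thermally stable area this
    percentage should stay nearly constant over time.
    """
    if not t_low < t_high:
        raise ValueError("t_low must be < t_high")
    frame = np.asarray(frame, dtype=float)
    if not roi.within(frame.shape):
        raise ValueError(f"{roi} outside frame {frame.shape}")
    patch = frame[roi.slices]
    inside = np.count_nonzero((patch >= t_low) & (patch <= t_high))
    return 100.0 * inside / patch.size


def flat_field_stats(frame: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, std, min, max) of a frame's pixel-value distribution.

    Applied to a recording of a uniform-temperature surface this summarises
    the camera's per-pixel noise.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    return (
        float(frame.mean()),
        float(frame.std()),
        float(frame.min()),
        float(frame.max()),
    )
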