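"""Synthetic thermal/depth breathing scenes with known ground truth.

No public recordings exist for this kind of paired thermal + depth
breathing data, so every downstream stage is exercised against simulated
sensor streams.  The thermal stream emulates a low-cost long-wave infrared
camera: a smooth warm face on a cooler background, a rectangular mouth
patch whose temperature oscillates at the breathing frequency, per-frame
8-bit grey quantisation against the frame's own temperature span, and a
calibration bar printing that span as raster digits.  The depth stream
emulates a time-of-flight sensor observing a chest patch whose distance
oscillates at the same frequency.

Everything is deterministic given the scene seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import BarLayout
from .glyphs import CELL_SHAPE, GLYPH_CLASSES, render_cell
from .types import ROI

__all__ = [
    "DepthFrame",
    "GroundTruth",
    "JitterParams",
    "SceneParams",
    "ThermalFrame",
    "default_chest_roi",
    "drift_path",
    "make_digit_training_set",
    "render_calibration_bar",
    "simulate_depth_sequence",
    "simulate_thermal_sequence",
]

#: Printable temperature limits of the emulated camera (degrees Celsius).
CAMERA_RANGE = (-40.0, 330.0)

#: Valid distance range of the emulated depth sensor (metres).
DEPTH_RANGE = (0.4, 4.0)


@dataclass(frozen=True)
class ThermalFrame:
    """One 8-bit grey thermal frame (calibration bar composited on top)."""

    grey: np.ndarray  # uint8, (rows, cols)
    index: int


@dataclass(frozen=True)
class DepthFrame:
    """One depth matrix: per-pixel distance from the sensor in metres."""

    values: np.ndarray  # float, (rows, cols)
    index: int


@dataclass(frozen=True)
class SceneParams:
    """Scene description shared by the thermal and depth simulators.

    The thermal frame includes the calibration bar in its top rows; the
    breathing scene (and all scene coordinates, e.g. the mouth trajectory)
    live in the region below the bar.
    """

    frame_shape: tuple[int, int] = (96, 128)
    fs: float = 10.0  # Hz
    duration: float = 300.0  # s
    breath_freq: float = 0.25  # Hz
    mouth_center_path: np.ndarray | None = None  # (n_frames, 2) scene coords
    mouth_size: tuple[int, int] = (10, 14)  # (rows, cols) px
    base_temp: float = 30.0  # degC, mouth mean
    breath_amplitude: float = 1.5  # degC
    temp_drift_rate: float = 0.1  # degC / min
    noise_std: float = 0.3  # degC, thermal pixel noise
    ambient_temp: float = 22.0  # degC background
    face_excess: float = 8.0  # degC face peak over ambient
    depth_shape: tuple[int, int] = (48, 64)
    chest_mean_dist: float = 1.5  # m
    chest_amplitude: float = 0.005  # m
    chest_size: tuple[int, int] = (24, 32)  # px
    depth_noise_std: float = 0.002  # m
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.05 <= self.breath_freq <= 1.5:
            raise ValueError("breath_freq must lie in the 0.05-1.5 Hz analysis band")
        if not self.fs > 2 * self.breath_freq:
            raise ValueError("fs must exceed twice the breathing frequency (Nyquist)")
        if self.noise_std < 0 or self.depth_noise_std < 0:
            raise ValueError("noise_std must be non-negative")
        nf = self.duration * self.fs
        if abs(nf - round(nf)) > 1e-9 or round(nf) < 2:
            raise ValueError("duration * fs must be an integer >= 2")
        if not DEPTH_RANGE[0] <= self.chest_mean_dist <= DEPTH_RANGE[1]:
            raise ValueError(f"chest_mean_dist outside sensor range {DEPTH_RANGE}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fs))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fs

    def with_(self, **kw) -> "SceneParams":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Per-frame ground truth recorded while simulating a scene."""

    breath_freq: float
    per_frame_mouth_roi: list[ROI] | None = None
    per_frame_mean_mouth_temp: np.ndarray | None = None
    tmin_tmax_per_frame: np.ndarray | None = None  # (n, 2)
    per_frame_chest_dist: np.ndarray | None = None
    chest_roi: ROI | None = None

    def validate(self, n_frames: int) -> None:
        for name in ("per_frame_mouth_roi", "per_frame_mean_mouth_temp",
                     "tmin_tmax_per_frame", "per_frame_chest_dist"):
            v = getattr(self, name)
            if v is not None and len(v) != n_frames:
                raise ValueError(f"{name} length {len(v)} != {n_frames} frames")
        if self.tmin_tmax_per_frame is not None:
            tt = np.asarray(self.tmin_tmax_per_frame)
            if not np.all(tt[:, 0] < tt[:, 1]):
                raise ValueError("ground-truth tmin must be < tmax in every frame")


@dataclass(frozen=True)
class JitterParams:
    """Random perturbations applied to OCR training glyphs."""

    shift_px: int = 2
    scale_range: tuple[float, float] = (0.85, 1.15)
    noise_std: float = 25.0  # grey levels

    @classmethod
    def none(cls) -> "JitterParams":
        return cls(shift_px=0, scale_range=(1.0, 1.0), noise_std=0.0)


def drift_path(
    center: tuple[float, float],
    n_frames: int,
    fs: float,
    amplitude_px: tuple[float, float] = (0.0, 20.0),
    freq_hz: float = 0.075,
    phase: float = 0.0,
) -> np.ndarray:
    """Sinusoidal head-drift trajectory for the mouth centre.

    Peak speed is ``amplitude * 2*pi*freq / fs`` px/frame; the defaults stay
    at or below 1 px/frame, the slow head movement the moving ROI is meant
    to follow.
    """
    t = np.arange(n_frames) / fs
    s = np.sin(2 * np.pi * freq_hz * t + phase)
    return np.stack(
        [center[0] + amplitude_px[0] * s, center[1] + amplitude_px[1] * s], axis=1
    )


def render_calibration_bar(tmin: float, tmax: float, layout: BarLayout) -> np.ndarray:
    """Render the calibration-bar image for one frame.

    The bar shows a horizontal grey wedge with the frame's minimum and
    maximum temperatures printed (one decimal place) as white raster digits
    on black, right-aligned in the layout's fixed-width character cells.
    """
    if not tmin < tmax:
        raise ValueError(f"degenerate temperature span ({tmin}, {tmax})")
    if tmin < CAMERA_RANGE[0] or tmax > CAMERA_RANGE[1]:
        raise ValueError(f"temperatures outside camera range {CAMERA_RANGE}")
    box = layout.bar_box
    img = np.zeros((box.height, box.width), dtype=np.uint8)
    g = layout.gradient_box
    ramp = np.linspace(0, 255, g.width).astype(np.uint8)
    img[g.r0 - box.r0 : g.r1 - box.r0, g.c0 - box.c0 : g.c1 - box.c0] = ramp
    for value, cells in ((tmin, layout.min_cells), (tmax, layout.max_cells)):
        text = f"{value:.1f}"
        if len(text) > len(cells):
            raise ValueError(f"value {text!r} needs more than {len(cells)} cells")
        for ch, cell in zip(text, cells[len(cells) - len(text) :]):
            patch = render_cell(ch, (cell.height, cell.width))
            img[cell.r0 - box.r0 : cell.r1 - box.r0, cell.c0 - box.c0 : cell.c1 - box.c0] = patch
    return img


def _mouth_rects(params: SceneParams, scene_shape: tuple[int, int]) -> list[ROI]:
    n = params.n_frames
    if params.mouth_center_path is None:
        center = (0.65 * scene_shape[0], 0.5 * scene_shape[1])
        path = np.tile(np.asarray(center, dtype=float), (n, 1))
    else:
        path = np.asarray(params.mouth_center_path, dtype=float)
        if path.shape != (n, 2):
            raise ValueError(f"mouth_center_path must have shape ({n}, 2)")
    h, w = params.mouth_size
    rects = []
    for r, c in path:
        r0 = int(round(r - h / 2.0))
        c0 = int(round(c - w / 2.0))
        if r0 < 0 or c0 < 0 or r0 + h > scene_shape[0] or c0 + w > scene_shape[1]:
            raise ValueError(
                f"mouth patch at ({r0}, {c0}) leaves scene bounds {scene_shape}"
            )
        rects.append(ROI(r0, c0, r0 + h, c0 + w))
    return rects


def _face_field(scene_shape: tuple[int, int], params: SceneParams) -> np.ndarray:
    rows, cols = scene_shape
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    rc, cc = rows / 2.0, cols / 2.0
    sr, sc = rows / 4.0, cols / 4.0
    bump = np.exp(-0.5 * (((r - rc) / sr) ** 2 + ((c - cc) / sc) ** 2))
    return params.ambient_temp + params.face_excess * bump


def simulate_thermal_sequence(
    params: SceneParams, layout: BarLayout | None = None
) -> tuple[list[ThermalFrame], GroundTruth]:
    """Simulate a thermal video: frames with calibration bars, plus truth.

    Each frame's temperature field is quantised to 8-bit grey against the
    frame's own (tmin, tmax) span rounded outward to one decimal place —
    the precision at which the bar prints them — so the printed bar is the
    exact inverse mapping for that frame.
    """
    if layout is None:
        layout = BarLayout.default(params.frame_shape)
    rows, cols = params.frame_shape
    bar_h = layout.height
    scene_shape = (rows - bar_h, cols)
    if scene_shape[0] < max(params.mouth_size[0], 8):
        raise ValueError("frame too short below the calibration bar")
    rects = _mouth_rects(params, scene_shape)
    face = _face_field(scene_shape, params)
    rng = np.random.default_rng(params.seed)
    t = params.times
    mouth_temp = (
        params.base_temp
        + params.temp_drift_rate / 60.0 * t
        + params.breath_amplitude * np.sin(2 * np.pi * params.breath_freq * t)
    )

    frames: list[ThermalFrame] = []
    means = np.empty(params.n_frames)
    spans = np.empty((params.n_frames, 2))
    for i in range(params.n_frames):
        scene = face.copy()
        scene[rects[i].slices] = mouth_temp[i]
        if params.noise_std > 0:
            scene += rng.normal(0.0, params.noise_std, scene_shape)
        means[i] = scene[rects[i].slices].mean()
        tmin = math.floor(scene.min() * 10.0) / 10.0
        tmax = math.ceil(scene.max() * 10.0) / 10.0
        if tmax - tmin < 0.1:
            tmax = tmin + 0.1
        spans[i] = (tmin, tmax)
        grey = np.clip(np.round((scene - tmin) / (tmax - tmin) * 255.0), 0, 255)
        full = np.zeros((rows, cols), dtype=np.uint8)
        full[layout.bar_box.slices] = render_calibration_bar(tmin, tmax, layout)
        full[bar_h:, :] = grey.astype(np.uint8)
        frames.append(ThermalFrame(grey=full, index=i))

    truth = GroundTruth(
        breath_freq=params.breath_freq,
        per_frame_mouth_roi=rects,
        per_frame_mean_mouth_temp=means,
        tmin_tmax_per_frame=spans,
    )
    truth.validate(params.n_frames)
    return frames, truth


def default_chest_roi(params: SceneParams) -> ROI:
    """Centred fixed chest region used by the depth simulator."""
    rows, cols = params.depth_shape
    h, w = params.chest_size
    r0 = (rows - h) // 2
    c0 = (cols - w) // 2
    roi = ROI(r0, c0, r0 + h, c0 + w)
    if not roi.within(params.depth_shape):
        raise ValueError(f"chest patch {roi} exceeds depth frame {params.depth_shape}")
    return roi


def simulate_depth_sequence(
    params: SceneParams,
) -> tuple[list[DepthFrame], GroundTruth]:
    """Simulate the depth stream: chest patch oscillating towards the sensor."""
    roi = default_chest_roi(params)
    rows, cols = params.depth_shape
    background = float(np.clip(params.chest_mean_dist + 0.8, *DEPTH_RANGE))
    rng = np.random.default_rng(params.seed + 1)  # independent of thermal noise
    t = params.times
    chest = params.chest_mean_dist + params.chest_amplitude * np.sin(
        2 * np.pi * params.breath_freq * t
    )
    frames: list[DepthFrame] = []
    dists = np.empty(params.n_frames)
    for i in range(params.n_frames):
        mat = np.full((rows, cols), background)
        mat[roi.slices] = chest[i]
        if params.depth_noise_std > 0:
            mat += rng.normal(0.0, params.depth_noise_std, mat.shape)
        np.clip(mat, DEPTH_RANGE[0], DEPTH_RANGE[1], out=mat)
        dists[i] = mat[roi.slices].mean()
        frames.append(DepthFrame(values=mat, index=i))
    truth = GroundTruth(
        breath_freq=params.breath_freq,
        per_frame_chest_dist=dists,
        chest_roi=roi,
    )
    truth.validate(params.n_frames)
    return frames, truth


def make_digit_training_set(
    n_per_class: int,
    jitter: JitterParams | None = None,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[str]]:
    """Labelled, jittered glyph renderings for classifier training.

    Returns ``n_per_class`` cells per character class (class-major order),
    deterministic given ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    jitter = jitter or JitterParams()
    rng = np.random.default_rng(seed)
    glyphs: list[np.ndarray] = []
    labels: list[str] = []
    for ch in GLYPH_CLASSES:
        for _ in range(n_per_class):
            s = jitter.shift_px
            shift = tuple(rng.integers(-s, s + 1, 2)) if s > 0 else (0, 0)
            lo, hi = jitter.scale_range
            scale = float(rng.uniform(lo, hi)) if hi > lo else lo
            glyphs.append(
                render_cell(
                    ch,
                    CELL_SHAPE,
                    shift=shift,
                    scale=scale,
                    noise_std=jitter.noise_std,
                    rng=rng,
                )
            )
            labels.append(ch)
    return glyphs, labels
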