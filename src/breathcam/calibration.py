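"""Adaptive thermal-image calibration.

Each thermal frame carries a calibration bar printing the frame's minimum
and maximum temperature.  A small two-layer neural network (sigmoid hidden
layer, softmax output) reads the printed characters, and the recovered
(tmin, tmax) pair maps 8-bit grey levels linearly to degrees Celsius:

    T(g) = tmin + g * (tmax - tmin) / 255

The network is deliberately shallow: the glyphs come from a fixed raster
font, so after normalisation (Otsu binarisation + ink centring) the classes
are nearly separable and plain full-batch gradient descent on the
cross-entropy reaches near-perfect accuracy.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .glyphs import CELL_SHAPE, GLYPH_CLASSES
from .types import ROI

__all__ = [
    "BarLayout",
    "CalibrationError",
    "DigitClassifier",
    "TemperatureScale",
    "TrainingError",
    "classify_glyph",
    "classifier_accuracy",
    "grey_to_temperature",
    "normalize_glyph",
    "read_calibration_bar",
    "train_digit_classifier",
]

_NUMBER_RE = re.compile(r"^-?\d+(\.\d+)?$")


class CalibrationError(RuntimeError):
    """Raised when a calibration bar cannot be parsed into (tmin, tmax)."""

    def __init__(self, message: str, frame_index: int | None = None):
        if frame_index is not None:
            message = f"frame {frame_index}: {message}"
        super().__init__(message)
        self.frame_index = frame_index


class TrainingError(RuntimeError):
    """Raised when classifier training diverges (non-finite loss)."""


@dataclass(frozen=True)
class TemperatureScale:
    """Frame temperature range: grey 0 maps to tmin, grey 255 to tmax."""

    tmin: float
    tmax: float

    def __post_init__(self) -> None:
        if not self.tmin < self.tmax:
            raise ValueError(f"tmin must be < tmax, got ({self.tmin}, {self.tmax})")


@dataclass(frozen=True)
class BarLayout:
    """Geometry of the calibration bar inside a frame.

    ``min_cells`` and ``max_cells`` are fixed-width character cells (frame
    coordinates) holding the printed minimum and maximum temperatures;
    ``gradient_box`` is the grey wedge drawn between them.
    """

    bar_box: ROI
    min_cells: tuple[ROI, ...]
    max_cells: tuple[ROI, ...]
    gradient_box: ROI

    def __post_init__(self) -> None:
        cells = list(self.min_cells) + list(self.max_cells)
        for cell in cells:
            if not (
                self.bar_box.r0 <= cell.r0
                and cell.r1 <= self.bar_box.r1
                and self.bar_box.c0 <= cell.c0
                and cell.c1 <= self.bar_box.c1
            ):
                raise ValueError("character cell outside bar box")
        for i, a in enumerate(cells):
            for b in cells[i + 1 :]:
                if a.iou(b) > 0:
                    raise ValueError("overlapping character cells")

    @classmethod
    def default(cls, frame_shape: tuple[int, int], n_cells: int = 6) -> "BarLayout":
        """Standard layout: min field left, grey wedge centre, max field right."""
        rows, cols = frame_shape
        ch, cw = CELL_SHAPE
        field_w = n_cells * cw
        if cols < 2 * field_w + 12 or rows < ch + 2:
            raise ValueError(f"frame {frame_shape} too small for default bar layout")
        bar = ROI(0, 0, ch + 2, cols)
        min_cells = tuple(
            ROI(1, 1 + i * cw, 1 + ch, 1 + (i + 1) * cw) for i in range(n_cells)
        )
        max_cells = tuple(
            ROI(1, cols - 1 - field_w + i * cw, 1 + ch, cols - 1 - field_w + (i + 1) * cw)
            for i in range(n_cells)
        )
        gradient = ROI(1, field_w + 4, 1 + ch, cols - field_w - 4)
        return cls(bar, min_cells, max_cells, gradient)

    @property
    def height(self) -> int:
        return self.bar_box.r1


@dataclass
class DigitClassifier:
    """Two-layer perceptron: sigmoid hidden layer, softmax output."""

    w1: np.ndarray  # (hidden, input_dim)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (classes, hidden)
    b2: np.ndarray  # (classes,)
    classes: tuple[str, ...]
    input_shape: tuple[int, int] = field(default=CELL_SHAPE)

    @property
    def input_dim(self) -> int:
        return int(self.w1.shape[1])

    @property
    def hidden_units(self) -> int:
        return int(self.w1.shape[0])

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for a batch of flattened glyphs."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.input_dim:
            raise ValueError(f"expected input dim {self.input_dim}, got {x.shape[1]}")
        h = _sigmoid(x @ self.w1.T + self.b1)
        return _softmax(h @ self.w2.T + self.b2)

    def save(self, path: str | Path) -> None:
        payload = {
            "classes": list(self.classes),
            "input_shape": list(self.input_shape),
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "DigitClassifier":
        d = json.loads(Path(path).read_text())
        return cls(
            w1=np.array(d["w1"], dtype=float),
            b1=np.array(d["b1"], dtype=float),
            w2=np.array(d["w2"], dtype=float),
            b2=np.array(d["b2"], dtype=float),
            classes=tuple(d["classes"]),
            input_shape=tuple(d["input_shape"]),
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def normalize_glyph(
    cell: np.ndarray, out_shape: tuple[int, int] = CELL_SHAPE
) -> np.ndarray:
    """Normalise a character cell to a binary glyph on a fixed canvas.

    The cell is binarised with Otsu's threshold and the ink bounding box is
    centred on the canvas (down-scaled, aspect preserved, if it does not
    fit).  A cell with no contrast — a blank padding cell — maps to the
    all-zero canvas.
    """
    img = np.asarray(cell, dtype=float)
    if img.ndim != 2:
        raise ValueError("glyph cell must be 2-D")
    if np.ptp(img) < 1e-9:
        return np.zeros(out_shape, dtype=float)
    ink = img > threshold_otsu(img)
    if not ink.any():
        return np.zeros(out_shape, dtype=float)
    rows = np.flatnonzero(ink.any(axis=1))
    cols = np.flatnonzero(ink.any(axis=0))
    crop = ink[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1].astype(float)
    if crop.shape[0] > out_shape[0] or crop.shape[1] > out_shape[1]:
        f = min(out_shape[0] / crop.shape[0], out_shape[1] / crop.shape[1])
        new_shape = (max(1, int(crop.shape[0] * f)), max(1, int(crop.shape[1] * f)))
        crop = (resize(crop, new_shape, order=1, anti_aliasing=False) > 0.5).astype(float)
    canvas = np.zeros(out_shape, dtype=float)
    r0 = (out_shape[0] - crop.shape[0]) // 2
    c0 = (out_shape[1] - crop.shape[1]) // 2
    canvas[r0 : r0 + crop.shape[0], c0 : c0 + crop.shape[1]] = crop
    return canvas


def _prepare(glyphs, input_shape) -> np.ndarray:
    return np.stack([normalize_glyph(g, input_shape).ravel() for g in glyphs])


def train_digit_classifier(
    glyphs,
    labels,
    hidden_units: int = 32,
    epochs: int = 600,
    lr: float = 2.0,
    seed: int = 0,
) -> DigitClassifier:
    """Train the bar-reading classifier with full-batch gradient descent.

    Inputs are normalised glyph cells; the loss is mean cross-entropy.
    Training is deterministic given ``seed`` (weight initialisation only —
    there is no stochastic batching).
    """
    labels = [str(l) for l in labels]
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError("need at least two character classes to train")
    shapes = {np.asarray(g).shape for g in glyphs}
    if len(shapes) != 1:
        raise ValueError(f"glyphs must share one shape, got {shapes}")
    input_shape = CELL_SHAPE
    x = _prepare(glyphs, input_shape)
    n, d = x.shape
    idx = {c: i for i, c in enumerate(classes)}
    t = np.zeros((n, len(classes)))
    t[np.arange(n), [idx[l] for l in labels]] = 1.0

    rng = np.random.default_rng(seed)
    w1 = rng.normal(0.0, 1.0 / np.sqrt(d), (hidden_units, d))
    b1 = np.zeros(hidden_units)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(hidden_units), (len(classes), hidden_units))
    b2 = np.zeros(len(classes))

    for _ in range(epochs):
        h = _sigmoid(x @ w1.T + b1)
        p = _softmax(h @ w2.T + b2)
        loss = -np.mean(np.sum(t * np.log(p + 1e-12), axis=1))
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite training loss: {loss}")
        dz2 = (p - t) / n  # softmax + cross-entropy gradient
        dw2 = dz2.T @ h
        db2 = dz2.sum(axis=0)
        dh = dz2 @ w2
        dz1 = dh * h * (1.0 - h)
        dw1 = dz1.T @ x
        db1 = dz1.sum(axis=0)
        w2 -= lr * dw2
        b2 -= lr * db2
        w1 -= lr * dw1
        b1 -= lr * db1

    return DigitClassifier(w1, b1, w2, b2, classes, input_shape)


def classify_glyph(model: DigitClassifier, glyph: np.ndarray) -> tuple[str, float]:
    """Classify one glyph cell; returns (label, softmax confidence).

    Ties in the softmax output resolve to the lowest class index.  The
    caller decides whether to reject low-confidence answers.
    """
    vec = normalize_glyph(glyph, model.input_shape).ravel()
    p = model.predict_proba(vec)[0]
    k = int(np.argmax(p))
    return model.classes[k], float(p[k])


def classifier_accuracy(model: DigitClassifier, glyphs, labels) -> float:
    """Fraction of glyphs classified correctly (no reject threshold)."""
    x = _prepare(glyphs, model.input_shape)
    pred = np.argmax(model.predict_proba(x), axis=1)
    idx = {c: i for i, c in enumerate(model.classes)}
    truth = np.array([idx[str(l)] for l in labels])
    return float(np.mean(pred == truth))


def _read_field(
    grey: np.ndarray,
    cells: tuple[ROI, ...],
    model: DigitClassifier,
    reject_threshold: float,
    frame_index: int | None,
    name: str,
) -> float:
    chars = []
    for cell in cells:
        patch = grey[cell.slices]
        vec = normalize_glyph(patch, model.input_shape)
        if not vec.any():  # blank padding cell
            continue
        label, conf = classify_glyph(model, patch)
        if conf < reject_threshold:
            raise CalibrationError(
                f"{name} field: low-confidence glyph (p={conf:.3f})", frame_index
            )
        chars.append(label)
    text = "".join(chars)
    if not _NUMBER_RE.match(text):
        raise CalibrationError(f"{name} field unparseable: {text!r}", frame_index)
    return float(text)


def read_calibration_bar(
    frame,
    layout: BarLayout,
    model: DigitClassifier,
    reject_threshold: float = 0.5,
    frame_index: int | None = None,
) -> TemperatureScale:
    """Read the printed (tmin, tmax) pair from a frame's calibration bar."""
    grey = np.asarray(getattr(frame, "grey", frame))
    if not layout.bar_box.within(grey.shape):
        raise CalibrationError("bar layout outside frame bounds", frame_index)
    tmin = _read_field(grey, layout.min_cells, model, reject_threshold, frame_index, "min")
    tmax = _read_field(grey, layout.max_cells, model, reject_threshold, frame_index, "max")
    if not tmin < tmax:
        raise CalibrationError(f"parsed tmin {tmin} >= tmax {tmax}", frame_index)
    return TemperatureScale(tmin, tmax)


def grey_to_temperature(grey_matrix: np.ndarray, scale: TemperatureScale) -> np.ndarray:
    """Map 8-bit grey levels to Celsius: T = tmin + g*(tmax-tmin)/255."""
    g = np.asarray(grey_matrix, dtype=float)
    if g.min() < 0 or g.max() > 255:
        raise ValueError("grey values outside [0, 255]")
    return scale.tmin + g * (scale.tmax - scale.tmin) / 255.0
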