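"""Raster glyphs used on the synthetic calibration bar.

The character set covers the digits 0-9 plus ``.`` and ``-`` so that both
decimal and sub-zero temperatures can be printed.  Each character is a 7x5
bitmap rendered into a fixed-size cell; the digit classifier is trained on
jittered renderings produced by the same routines.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import zoom

#: Classes recognised by the digit classifier, in label order.
GLYPH_CLASSES: tuple[str, ...] = tuple("0123456789") + (".", "-")

#: Character-cell shape (rows, cols) used by the bar renderer and the OCR.
CELL_SHAPE: tuple[int, int] = (12, 8)

_FONT_ROWS = {
    "0": ("01110", "10001", "10011", "10101", "11001", "10001", "01110"),
    "1": ("00100", "01100", "00100", "00100", "00100", "00100", "01110"),
    "2": ("01110", "10001", "00001", "00010", "00100", "01000", "11111"),
    "3": ("11111", "00010", "00100", "00010", "00001", "10001", "01110"),
    "4": ("00010", "00110", "01010", "10010", "11111", "00010", "00010"),
    "5": ("11111", "10000", "11110", "00001", "00001", "10001", "01110"),
    "6": ("00110", "01000", "10000", "11110", "10001", "10001", "01110"),
    "7": ("11111", "00001", "00010", "00100", "01000", "01000", "01000"),
    "8": ("01110", "10001", "10001", "01110", "10001", "10001", "01110"),
    "9": ("01110", "10001", "10001", "01111", "00001", "00010", "01100"),
    ".": ("00000", "00000", "00000", "00000", "00000", "00110", "00110"),
    "-": ("00000", "00000", "00000", "11111", "00000", "00000", "00000"),
}


def glyph_bitmap(char: str) -> np.ndarray:
    """7x5 boolean bitmap for one supported character."""
    try:
        rows = _FONT_ROWS[char]
    except KeyError:
        raise ValueError(f"unsupported glyph {char!r}") from None
    return np.array([[c == "1" for c in row] for row in rows], dtype=bool)


def render_cell(
    char: str,
    cell_shape: tuple[int, int] = CELL_SHAPE,
    shift: tuple[int, int] = (0, 0),
    scale: float = 1.0,
    noise_std: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one character into a uint8 cell (foreground 255 on 0).

    ``shift`` displaces the glyph in pixels, ``scale`` resizes the bitmap
    (nearest-neighbour-ish bilinear + re-threshold) and ``noise_std`` adds
    Gaussian grey-level noise; these are the jitter knobs used when building
    OCR training sets.
    """
    bitmap = glyph_bitmap(char)
    if scale != 1.0:
        bitmap = zoom(bitmap.astype(float), scale, order=1) > 0.5
        if bitmap.size == 0 or not bitmap.any():
            bitmap = glyph_bitmap(char)  # degenerate down-scale: keep original
    cell = np.zeros(cell_shape, dtype=float)
    gh, gw = bitmap.shape
    r0 = (cell_shape[0] - gh) // 2 + shift[0]
    c0 = (cell_shape[1] - gw) // 2 + shift[1]
    r0 = int(np.clip(r0, 0, cell_shape[0] - gh))
    c0 = int(np.clip(c0, 0, cell_shape[1] - gw))
    cell[r0 : r0 + gh, c0 : c0 + gw] = bitmap * 255.0
    if noise_std > 0:
        if rng is None:
            rng = np.random.default_rng()
        cell = cell + rng.normal(0.0, noise_std, cell.shape)
    return np.clip(np.round(cell), 0, 255).astype(np.uint8)
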