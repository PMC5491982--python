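"""Shared geometric primitives."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class ROI:
    """Axis-aligned rectangular region, 0-based, half-open [r0, r1) x [c0, c1).

    Coordinates are row-major with the origin at the top-left corner,
    matching NumPy indexing so that ``frame[roi.slices]`` crops the region.
    """

    r0: int
    c0: int
    r1: int
    c1: int

    def __post_init__(self) -> None:
        if not (self.r0 < self.r1 and self.c0 < self.c1):
            raise ValueError(f"degenerate ROI {self!r}")
        if self.r0 < 0 or self.c0 < 0:
            raise ValueError(f"negative ROI origin {self!r}")

    @property
    def height(self) -> int:
        return self.r1 - self.r0

    @property
    def width(self) -> int:
        return self.c1 - self.c0

    @property
    def area(self) -> int:
        return self.height * self.width

    @property
    def center(self) -> tuple[float, float]:
        return ((self.r0 + self.r1 - 1) / 2.0, (self.c0 + self.c1 - 1) / 2.0)

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.r0, self.r1), slice(self.c0, self.c1)

    def within(self, shape: tuple[int, int]) -> bool:
        return self.r1 <= shape[0] and self.c1 <= shape[1]

    def shift(self, dr: int, dc: int) -> "ROI":
        return ROI(self.r0 + dr, self.c0 + dc, self.r1 + dr, self.c1 + dc)

    def iou(self, other: "ROI") -> float:
        """Intersection-over-union of two regions (0 when disjoint)."""
        rh = min(self.r1, other.r1) - max(self.r0, other.r0)
        cw = min(self.c1, other.c1) - max(self.c0, other.c0)
        inter = max(rh, 0) * max(cw, 0)
        union = self.area + other.area - inter
        return inter / union

    def to_list(self) -> list[int]:
        return [self.r0, self.c0, self.r1, self.c1]
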