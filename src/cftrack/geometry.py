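"""Axis-aligned bounding-box geometry.

Boxes are the unit of tracker output and of evaluation: the overlap score
(intersection-over-union) and the center error between a predicted and a
ground-truth box are the two primitives every tracking metric is built from.

Internal convention: 0-based, half-open — pixel column ``c`` belongs to a box
iff ``x <= c < x + w`` (rows likewise).  Areas are continuous (real-valued),
so sub-pixel boxes behave sensibly; on integer boxes the continuous IoU
coincides with the pixel-set count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned target region, 0-based half-open, ``w, h > 0``."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box sides must be positive, got w={self.w}, h={self.h}")
        for v in (self.x, self.y, self.w, self.h):
            if not math.isfinite(v):
                raise ValueError("box coordinates must be finite")

    @property
    def center(self) -> tuple[float, float]:
        """(cx, cy) — the box center in pixel coordinates."""
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def area(self) -> float:
        return self.w * self.h

    @classmethod
    def from_center(cls, cx: float, cy: float, w: float, h: float) -> "BoundingBox":
        return cls(cx - w / 2.0, cy - h / 2.0, w, h)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x, self.y, self.w, self.h)


def overlap_score(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes using continuous areas.

    Returns a value in [0, 1]; 0 when the boxes are disjoint, 1 iff they
    coincide.
    """
    if a == b:
        return 1.0
    ix = min(a.x + a.w, b.x + b.w) - max(a.x, b.x)
    iy = min(a.y + a.h, b.y + b.h) - max(a.y, b.y)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    return min(max(inter / union, 0.0), 1.0)


def center_error(a: BoundingBox, b: BoundingBox) -> float:
    """Euclidean distance in pixels between the two box centers."""
    (ax, ay), (bx, by) = a.center, b.center
    return math.hypot(ax - bx, ay - by)
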