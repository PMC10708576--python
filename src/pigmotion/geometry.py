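"""Axis-aligned bounding boxes and the box arithmetic shared by the tracker,
movement, and evaluation modules.

Conventions
-----------
Image coordinates are 0-based with origin at the top-left corner, x growing
rightward and y downward.  A box is ``(x, y, w, h)`` = (left, top, width,
height) and covers the half-open region ``[x, x+w) x [y, y+h)`` — the same
semantics as MOTChallenge CSV files.  Boxes are real-valued throughout;
discretization to integer pixels happens only in :func:`pixel_set`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BBox",
    "Detection",
    "Point",
    "iou",
    "iou_matrix",
    "center",
    "clip_box",
    "pixel_set",
]


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box: left, top, width, height in pixels (w, h >= 0)."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (np.isfinite([self.x, self.y, self.w, self.h]).all()):
            raise ValueError(f"box coordinates must be finite, got {self}")
        if self.w < 0 or self.h < 0:
            raise ValueError(f"box width/height must be non-negative, got {self}")

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def right(self) -> float:
        return self.x + self.w

    @property
    def bottom(self) -> float:
        return self.y + self.h

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x, self.y, self.w, self.h)


@dataclass(frozen=True)
class Point:
    """Sub-pixel image location."""

    px: float
    py: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.px) and np.isfinite(self.py)):
            raise ValueError(f"point coordinates must be finite, got {self}")


@dataclass(frozen=True)
class Detection:
    """A scored detector output box on one frame (0-based frame index)."""

    box: BBox
    score: float
    frame: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"detection score must be in [0, 1], got {self.score}")


def center(b: BBox) -> Point:
    """Center point of a box, ``(x + w/2, y + h/2)``."""
    return Point(b.x + b.w / 2.0, b.y + b.h / 2.0)


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two boxes.

    Degenerate (zero-area) boxes have IoU 0 against anything, including
    themselves, so they never win an association.
    """
    ix = min(a.right, b.right) - max(a.x, b.x)
    iy = min(a.bottom, b.bottom) - max(a.y, b.y)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    if union <= 0:
        return 0.0
    # (x+w)-x need not equal w in floating point; clamp to the unit interval
    return min(max(inter / union, 0.0), 1.0)


def iou_matrix(boxes_a: list[BBox], boxes_b: list[BBox]) -> np.ndarray:
    """Pairwise IoU, shape ``(len(boxes_a), len(boxes_b))``, vectorized."""
    if not boxes_a or not boxes_b:
        return np.zeros((len(boxes_a), len(boxes_b)))
    A = np.array([b.as_tuple() for b in boxes_a], dtype=float)
    B = np.array([b.as_tuple() for b in boxes_b], dtype=float)
    ax1, ay1 = A[:, 0:1], A[:, 1:2]
    ax2, ay2 = ax1 + A[:, 2:3], ay1 + A[:, 3:4]
    bx1, by1 = B[None, :, 0], B[None, :, 1]
    bx2, by2 = bx1 + B[None, :, 2], by1 + B[None, :, 3]
    iw = np.minimum(ax2, bx2) - np.maximum(ax1, bx1)
    ih = np.minimum(ay2, by2) - np.maximum(ay1, by1)
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    union = A[:, 2:3] * A[:, 3:4] + (B[None, :, 2] * B[None, :, 3]) - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return np.clip(out, 0.0, 1.0)


def clip_box(b: BBox, width: float, height: float) -> BBox:
    """Intersect a box with the frame ``[0, width) x [0, height)``.

    A box lying fully outside collapses to a zero-area box pinned at the
    nearest frame border.
    """
    if width <= 0 or height <= 0:
        raise ValueError("frame dimensions must be positive")
    x1 = min(max(b.x, 0.0), width)
    y1 = min(max(b.y, 0.0), height)
    x2 = min(max(b.right, 0.0), width)
    y2 = min(max(b.bottom, 0.0), height)
    return BBox(x1, y1, max(x2 - x1, 0.0), max(y2 - y1, 0.0))


def pixel_set(b: BBox, width: int, height: int) -> set[tuple[int, int]]:
    """Integer pixels ``(u, v)`` whose centers fall inside the clipped box.

    The left/top edges round to the nearest grid line and the pixel count
    per axis is the rounded width/height, so an interior box always covers
    exactly ``round(w) * round(h)`` pixels; clipping to the frame can only
    shrink that.
    """
    if width <= 0 or height <= 0:
        raise ValueError("frame dimensions must be positive")
    u0, v0 = int(round(b.x)), int(round(b.y))
    u1, v1 = u0 + int(round(b.w)), v0 + int(round(b.h))
    u0, v0 = max(u0, 0), max(v0, 0)
    u1, v1 = min(u1, int(width)), min(v1, int(height))
    return {(u, v) for v in range(v0, v1) for u in range(u0, u1)}


def pixel_slices(b: BBox, width: int, height: int) -> tuple[slice, slice] | None:
    """Rectangular (row, col) slices covering :func:`pixel_set`, or None if empty.

    Fast path for array indexing; the set form exists for its contract.
    """
    u0, v0 = int(round(b.x)), int(round(b.y))
    u1, v1 = u0 + int(round(b.w)), v0 + int(round(b.h))
    u0, v0 = max(u0, 0), max(v0, 0)
    u1, v1 = min(u1, int(width)), min(v1, int(height))
    if u1 <= u0 or v1 <= v0:
        return None
    return slice(v0, v1), slice(u0, u1)
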