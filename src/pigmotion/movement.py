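"""Per-animal movement estimators.

Three ways to turn tracks and flow into a per-frame movement number M (in
pixels) for each identity:

``bbox_center``
    Euclidean distance between the track box centers of consecutive frames.
    Cheap, but jittering detection boxes around a stationary animal read as
    motion, and box shrinkage under occlusion reads as large motion.

``rep_point``
    A representative point (the center of the track's first box) is carried
    through the flow field frame by frame; M is the magnitude of the flow
    at the point's current position.

``box_mean_flow``
    M is the mean flow magnitude over all pixels inside the track's box —
    the default, since it sees the whole animal (head shakes included) and
    is immune to box jitter when the animal is still.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flow import FlowField, flow_at
from .geometry import BBox, Point, center, pixel_slices
from .tracker import Track

__all__ = [
    "METHODS",
    "MovementRecord",
    "MovementSeries",
    "bbox_center_movement",
    "rep_point_movement",
    "propagate_point",
    "box_mean_flow_movement",
    "per_track_movement",
    "cumulative",
]

METHODS = ("bbox_center", "rep_point", "box_mean_flow")


@dataclass(frozen=True)
class MovementRecord:
    """Movement of one identity from ``frame`` to ``frame + 1``, in pixels."""

    track_id: int
    frame: int
    method: str
    value: float

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not (np.isfinite(self.value) and self.value >= 0):
            raise ValueError(f"movement must be finite and >= 0, got {self.value}")


@dataclass
class MovementSeries:
    """Ordered per-track movement records plus running totals."""

    records: dict[int, list[MovementRecord]] = field(default_factory=dict)
    cumulative: dict[int, list[float]] = field(default_factory=dict)

    def add(self, rec: MovementRecord) -> None:
        recs = self.records.setdefault(rec.track_id, [])
        if recs and rec.frame <= recs[-1].frame:
            raise ValueError("records must be added in increasing frame order")
        recs.append(rec)
        cum = self.cumulative.setdefault(rec.track_id, [])
        cum.append((cum[-1] if cum else 0.0) + rec.value)

    def total(self, track_id: int) -> float:
        cum = self.cumulative.get(track_id)
        return cum[-1] if cum else 0.0

    def track_ids(self) -> list[int]:
        return sorted(self.records)


def bbox_center_movement(box_t: BBox, box_t1: BBox) -> float:
    """Distance between the two boxes' centers."""
    c0, c1 = center(box_t), center(box_t1)
    return float(np.hypot(c1.px - c0.px, c1.py - c0.py))


def rep_point_movement(F: FlowField, p: Point) -> float:
    """Flow magnitude at the representative point."""
    dx, dy = flow_at(F, p)
    return float(np.hypot(dx, dy))


def propagate_point(p: Point, F: FlowField) -> Point:
    """Advance the representative point by the local flow, clipped in-bounds."""
    dx, dy = flow_at(F, p)
    return Point(
        float(np.clip(p.px + dx, 0.0, F.width - 1)),
        float(np.clip(p.py + dy, 0.0, F.height - 1)),
    )


def box_mean_flow_movement(F: FlowField, box: BBox) -> float:
    """Mean flow magnitude over the pixels inside the (clipped) box."""
    sl = pixel_slices(box, F.width, F.height)
    if sl is None:
        raise ValueError(f"box {box} covers no pixels of the {F.width}x{F.height} frame")
    rows, cols = sl
    mag = np.hypot(F.du[rows, cols], F.dv[rows, cols])
    return float(mag.mean())


def per_track_movement(
    tracks: list[Track],
    flows: dict[int, FlowField],
    method: str = "box_mean_flow",
) -> MovementSeries:
    """Movement series for every track under one estimator.

    ``flows[t]`` is the forward flow from frame t to frame t+1.  A record
    is produced for each frame pair (t, t+1) on which the track has a box
    at both ends; gaps (lost frames) contribute nothing.  The box anchoring
    a pair is the one at frame t, since forward flow lives on frame t.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    series = MovementSeries()
    for track in sorted(tracks, key=lambda t: t.track_id):
        frames = sorted(track.boxes)
        if len(frames) < 2:
            continue
        rep: Point | None = None
        if method == "rep_point":
            rep = center(track.boxes[frames[0]])
        for f0, f1 in zip(frames[:-1], frames[1:]):
            if f1 != f0 + 1:
                continue  # gap while lost: no record
            if method == "bbox_center":
                value = bbox_center_movement(track.boxes[f0], track.boxes[f1])
            else:
                if f0 not in flows:
                    raise KeyError(f"no flow field for frame pair ({f0}, {f0 + 1})")
                F = flows[f0]
                if method == "rep_point":
                    assert rep is not None
                    value = rep_point_movement(F, rep)
                    rep = propagate_point(rep, F)
                else:
                    value = box_mean_flow_movement(F, track.boxes[f0])
            series.add(MovementRecord(track.track_id, f0, method, value))
    return series


def cumulative(series: MovementSeries) -> MovementSeries:
    """Recompute running sums from the records (idempotent)."""
    out = MovementSeries()
    for tid in series.track_ids():
        for rec in series.records[tid]:
            out.add(rec)
    return out
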