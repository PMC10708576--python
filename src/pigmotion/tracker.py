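"""Two-stage IoU association tracker (BYTE) with Kalman motion prediction.

One tracking step splits the frame's detections by confidence, matches
high-score detections to the Kalman-predicted boxes of all live tracks
first, then gives low-score detections — typically partially occluded
animals — a second chance against the still-unmatched tracks.  Unmatched
high-score detections seed new tracks; unmatched tracks linger as ``lost``
for a bounded number of frames before removal.  This recovers occluded
animals without spawning identities from detector noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import BBox, Detection, iou_matrix
from .kalman import KalmanState, kf_initiate, kf_predict, kf_update

__all__ = [
    "TrackStatus",
    "Track",
    "TrackerConfig",
    "split_detections",
    "associate",
    "nms",
    "byte_step",
    "track_sequence",
    "ByteTracker",
]


class TrackStatus(Enum):
    ACTIVE = "active"
    LOST = "lost"
    REMOVED = "removed"


@dataclass
class Track:
    """One identity: Kalman belief plus per-frame box history."""

    track_id: int
    state: KalmanState
    boxes: dict[int, BBox] = field(default_factory=dict)
    status: TrackStatus = TrackStatus.ACTIVE
    frames_since_update: int = 0

    @property
    def first_frame(self) -> int:
        return min(self.boxes)

    @property
    def last_frame(self) -> int:
        return max(self.boxes)


@dataclass
class TrackerConfig:
    """Tracker thresholds.

    tau: high/low confidence split. det_thresh: floor below which detections
    are discarded outright. match_thresh_high/low: minimum IoU accepted in
    the first and second association stages. max_lost_frames: how long a
    lost track is retained before removal. max_tracks: cap on simultaneously
    retained tracks. nms_thresh: IoU threshold of the greedy
    non-maximum-suppression pass applied to raw detections.
    """

    tau: float = 0.5
    det_thresh: float = 0.1
    match_thresh_high: float = 0.5
    match_thresh_low: float = 0.5
    max_lost_frames: int = 30
    max_tracks: int = 100
    nms_thresh: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.det_thresh <= self.tau <= 1.0):
            raise ValueError("need 0 <= det_thresh <= tau <= 1")
        for name in ("match_thresh_high", "match_thresh_low", "nms_thresh"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.max_lost_frames < 0 or self.max_tracks < 1:
            raise ValueError("max_lost_frames >= 0 and max_tracks >= 1 required")


def split_detections(
    dets: list[Detection], config: TrackerConfig
) -> tuple[list[Detection], list[Detection]]:
    """Partition one frame's detections into (D_high, D_low), order preserved.

    Scores below ``det_thresh`` are discarded; scores above ``tau`` are
    high-confidence, the remainder low-confidence.
    """
    d_high = [d for d in dets if d.score > config.tau]
    d_low = [d for d in dets if config.det_thresh <= d.score <= config.tau]
    return d_high, d_low


def nms(dets: list[Detection], thresh: float) -> list[Detection]:
    """Greedy non-maximum suppression by descending score.

    Ties broken by input order so runs are reproducible.
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    boxes = [d.box for d in dets]
    M = iou_matrix(boxes, boxes)
    keep: list[int] = []
    for i in order:
        if all(M[i, j] <= thresh for j in keep):
            keep.append(i)
    return [dets[i] for i in sorted(keep)]


def associate(
    pred_boxes: list[BBox], det_boxes: list[BBox], iou_gate: float
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Globally optimal IoU assignment between track and detection boxes.

    Minimizes total ``1 - IoU`` over a maximum matching (Hungarian method),
    then demotes any assigned pair whose IoU falls below ``iou_gate``.
    Returns (matched (track_idx, det_idx) pairs, unmatched track indices,
    unmatched detection indices), pairs sorted lexicographically.
    """
    if not (0.0 <= iou_gate <= 1.0):
        raise ValueError("iou_gate must be in [0, 1]")
    n, m = len(pred_boxes), len(det_boxes)
    if n == 0 or m == 0:
        return [], list(range(n)), list(range(m))
    cost = 1.0 - iou_matrix(pred_boxes, det_boxes)
    rows, cols = linear_sum_assignment(cost)
    matched = []
    for r, c in zip(rows, cols):
        if 1.0 - cost[r, c] >= iou_gate and cost[r, c] < 1.0:
            matched.append((int(r), int(c)))
    matched.sort()
    mr = {r for r, _ in matched}
    mc = {c for _, c in matched}
    return (
        matched,
        [i for i in range(n) if i not in mr],
        [j for j in range(m) if j not in mc],
    )


class ByteTracker:
    """Stateful frame-by-frame tracker; :func:`track_sequence` wraps it."""

    def __init__(self, config: TrackerConfig | None = None):
        self.config = config or TrackerConfig()
        self.tracks: list[Track] = []  # all tracks ever created
        self._next_id = 1

    @property
    def live_tracks(self) -> list[Track]:
        return [t for t in self.tracks if t.status is not TrackStatus.REMOVED]

    def _new_track(self, det: Detection) -> Track:
        t = Track(track_id=self._next_id, state=kf_initiate(det.box))
        t.boxes[det.frame] = det.box
        self._next_id += 1
        self.tracks.append(t)
        return t

    def step(self, dets: list[Detection], frame: int) -> list[Track]:
        """Process one frame's detections; returns currently active tracks."""
        cfg = self.config
        if any(d.frame != frame for d in dets):
            raise ValueError("all detections in a step must share one frame index")

        dets = nms(dets, cfg.nms_thresh)
        d_high, d_low = split_detections(dets, cfg)

        # Kalman prediction for every live track, lost ones included
        live = self.live_tracks
        for t in live:
            t.state = kf_predict(t.state)
        pred_boxes = [t.state.to_box() for t in live]

        # stage 1: live tracks vs high-confidence detections
        matched1, um_tracks, um_high = associate(
            pred_boxes, [d.box for d in d_high], cfg.match_thresh_high
        )
        # stage 2: remaining tracks vs low-confidence detections
        remain = [live[i] for i in um_tracks]
        matched2, um_remain, _ = associate(
            [t.state.to_box() for t in remain], [d.box for d in d_low], cfg.match_thresh_low
        )

        for r, c in matched1:
            self._mark_matched(live[r], d_high[c])
        for r, c in matched2:
            self._mark_matched(remain[r], d_low[c])

        # unmatched tracks turn (or stay) lost; stale ones are removed
        for t in (remain[i] for i in um_remain):
            t.frames_since_update += 1
            if t.frames_since_update > cfg.max_lost_frames:
                t.status = TrackStatus.REMOVED
            else:
                t.status = TrackStatus.LOST

        # unmatched high-confidence detections start new tracks immediately
        for j in um_high:
            self._new_track(d_high[j])

        self._enforce_cap()
        return [t for t in self.tracks if t.status is TrackStatus.ACTIVE]

    def _mark_matched(self, t: Track, det: Detection) -> None:
        t.state = kf_update(t.state, det.box)
        t.boxes[det.frame] = det.box
        t.status = TrackStatus.ACTIVE
        t.frames_since_update = 0

    def _enforce_cap(self) -> None:
        live = self.live_tracks
        excess = len(live) - self.config.max_tracks
        if excess <= 0:
            return
        # evict longest-lost first; among equals the smallest id goes first
        victims = sorted(live, key=lambda t: (-t.frames_since_update, t.track_id))
        for t in victims[:excess]:
            t.status = TrackStatus.REMOVED


def byte_step(
    tracks: list[Track], dets: list[Detection], config: TrackerConfig
) -> list[Track]:
    """One frame of the two-stage association, functional form.

    Mutates and returns the given track list extended with any new tracks.
    """
    tracker = ByteTracker(config)
    tracker.tracks = tracks
    tracker._next_id = max((t.track_id for t in tracks), default=0) + 1
    frame = dets[0].frame if dets else (max((t.last_frame for t in tracks), default=-1) + 1)
    tracker.step(dets, frame)
    return tracker.tracks


def track_sequence(
    dets_by_frame: dict[int, list[Detection]], config: TrackerConfig | None = None
) -> list[Track]:
    """Track a whole sequence; returns every track ever created.

    Frame indices must be contiguous.  Frames with no detections still
    advance the tracker (prediction and lost-track aging run regardless).
    """
    config = config or TrackerConfig()
    if not dets_by_frame:
        return []
    frames = sorted(dets_by_frame)
    if frames[-1] - frames[0] + 1 != len(frames):
        raise ValueError("frame indices must be contiguous")
    tracker = ByteTracker(config)
    for f in frames:
        tracker.step(dets_by_frame[f], f)
    return tracker.tracks
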