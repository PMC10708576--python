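"""CLEAR and Identity multi-object-tracking evaluation.

CLEAR counts per-frame detection outcomes — true positives (CTP), false
positives (CFP), misses (CFN) and identity switches (IDSW) — using the
MOTChallenge convention: correspondences from the previous frame are kept
while still within the IoU gate, and only the remainder is re-matched by
optimal assignment.  MOTA = 1 - (CFN + CFP + IDSW) / GT.

Identity metrics choose one global bijection between ground-truth and
predicted identities that minimizes the total number of mismatched
frame-entries; IDTP/IDFP/IDFN count frame-entries covered/not covered by
that mapping and IDF1 = 2*IDTP / (2*IDTP + IDFP + IDFN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import BBox, iou, iou_matrix

__all__ = [
    "FrameAnnotations",
    "MetricReport",
    "clear_match",
    "mota_from_counts",
    "identity_match",
    "idf1_from_counts",
    "evaluate_annotations",
    "evaluate",
]


@dataclass
class FrameAnnotations:
    """Ground-truth and predicted (identity, box) entries per frame."""

    gt: dict[int, list[tuple[int, BBox]]] = field(default_factory=dict)
    pred: dict[int, list[tuple[int, BBox]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for side in (self.gt, self.pred):
            for f, entries in side.items():
                ids = [i for i, _ in entries]
                if len(ids) != len(set(ids)):
                    raise ValueError(f"duplicate identity within frame {f}")

    def frames(self) -> list[int]:
        return sorted(set(self.gt) | set(self.pred))

    def total_gt(self) -> int:
        return sum(len(v) for v in self.gt.values())

    def total_pred(self) -> int:
        return sum(len(v) for v in self.pred.values())


@dataclass
class MetricReport:
    CTP: int
    CFP: int
    CFN: int
    IDSW: int
    MOTA: float
    IDTP: int
    IDFP: int
    IDFN: int
    IDF1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "CTP": self.CTP, "CFP": self.CFP, "CFN": self.CFN,
            "IDSW": self.IDSW, "MOTA": self.MOTA,
            "IDTP": self.IDTP, "IDFP": self.IDFP, "IDFN": self.IDFN,
            "IDF1": self.IDF1,
        }

    def __str__(self) -> str:
        d = self.as_dict()
        lines = [f"{k:>6}  {v:.1f}" if isinstance(v, float) else f"{k:>6}  {v}"
                 for k, v in d.items()]
        return "\n".join(lines)


def _match_frame(
    gt_entries: list[tuple[int, BBox]],
    pred_entries: list[tuple[int, BBox]],
    prev: dict[int, int],
    gate: float,
) -> dict[int, int]:
    """One frame's GT-id -> pred-id correspondence (kept pairs + optimal rest)."""
    gt_ids = [g for g, _ in gt_entries]
    pred_ids = [p for p, _ in pred_entries]
    gt_boxes = {g: b for g, b in gt_entries}
    pred_boxes = {p: b for p, b in pred_entries}

    matches: dict[int, int] = {}
    # keep still-valid pairs from the previous frame
    for g in gt_ids:
        p = prev.get(g)
        if p is not None and p in pred_boxes and p not in matches.values():
            v = iou(gt_boxes[g], pred_boxes[p])
            if v >= gate and v > 0:
                matches[g] = p
    rem_g = [g for g in gt_ids if g not in matches]
    used_p = set(matches.values())
    rem_p = [p for p in pred_ids if p not in used_p]
    if rem_g and rem_p:
        M = iou_matrix([gt_boxes[g] for g in rem_g], [pred_boxes[p] for p in rem_p])
        feasible = (M >= gate) & (M > 0)
        # big-M makes the assignment maximize matched pairs first, then IoU
        cost = np.where(feasible, 1.0 - M, 1e6)
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            if feasible[r, c]:
                matches[rem_g[r]] = rem_p[c]
    return matches


def clear_match(
    annotations: FrameAnnotations, iou_gate: float = 0.5
) -> tuple[int, int, int, int]:
    """CLEAR counting pass; returns (CTP, CFP, CFN, IDSW).

    Identity memory persists over gaps: a switch is counted against a
    ground-truth identity's most recent previous matched prediction.
    """
    ctp = cfp = cfn = idsw = 0
    prev: dict[int, int] = {}  # frame-to-frame correspondence
    last_match: dict[int, int] = {}  # most recent match ever, for IDSW
    for f in annotations.frames():
        gt_entries = annotations.gt.get(f, [])
        pred_entries = annotations.pred.get(f, [])
        matches = _match_frame(gt_entries, pred_entries, prev, iou_gate)
        ctp += len(matches)
        cfn += len(gt_entries) - len(matches)
        cfp += len(pred_entries) - len(matches)
        for g, p in matches.items():
            if g in last_match and last_match[g] != p:
                idsw += 1
            last_match[g] = p
        prev = matches
    return ctp, cfp, cfn, idsw


def mota_from_counts(CFN: int, CFP: int, IDSW: int, GT_total: int) -> float:
    """MOTA as a percentage: 100 * (1 - (CFN + CFP + IDSW) / GT_total)."""
    if GT_total <= 0:
        raise ValueError("GT_total must be positive")
    return 100.0 * (1.0 - (CFN + CFP + IDSW) / GT_total)


def identity_match(
    annotations: FrameAnnotations, iou_gate: float = 0.5
) -> tuple[int, int, int]:
    """Globally optimal identity mapping; returns (IDTP, IDFP, IDFN).

    A GT entry and a predicted entry can only count as the same animal on a
    frame if their IoU clears the gate; the bijection between identities is
    chosen once for the whole sequence to minimize total mismatches.
    """
    gt_len: dict[int, int] = {}
    pred_len: dict[int, int] = {}
    overlap: dict[tuple[int, int], int] = {}
    for f in annotations.frames():
        gt_entries = annotations.gt.get(f, [])
        pred_entries = annotations.pred.get(f, [])
        for g, _ in gt_entries:
            gt_len[g] = gt_len.get(g, 0) + 1
        for p, _ in pred_entries:
            pred_len[p] = pred_len.get(p, 0) + 1
        if gt_entries and pred_entries:
            M = iou_matrix([b for _, b in gt_entries], [b for _, b in pred_entries])
            for i, (g, _) in enumerate(gt_entries):
                for j, (p, _) in enumerate(pred_entries):
                    if M[i, j] >= iou_gate and M[i, j] > 0:
                        overlap[(g, p)] = overlap.get((g, p), 0) + 1

    gt_ids = sorted(gt_len)
    pred_ids = sorted(pred_len)
    n, m = len(gt_ids), len(pred_ids)
    total_gt = sum(gt_len.values())
    total_pred = sum(pred_len.values())
    if n == 0 or m == 0:
        return 0, total_pred, total_gt

    # square cost with dummy rows/cols so identities may stay unmatched
    size = n + m
    cost = np.zeros((size, size))
    for i, g in enumerate(gt_ids):
        cost[i, m:] = gt_len[g]  # g left unmatched: all its entries are IDFN
        for j, p in enumerate(pred_ids):
            ov = overlap.get((g, p), 0)
            cost[i, j] = (gt_len[g] - ov) + (pred_len[p] - ov)
    for j, p in enumerate(pred_ids):
        cost[n:, j] = pred_len[p]  # p unmatched: all its entries are IDFP
    rows, cols = linear_sum_assignment(cost)
    min_cost = float(cost[rows, cols].sum())
    idtp = int(round((total_gt + total_pred - min_cost) / 2))
    return idtp, total_pred - idtp, total_gt - idtp


def idf1_from_counts(IDTP: int, IDFP: int, IDFN: int) -> float:
    """IDF1 as a percentage: 100 * 2*IDTP / (2*IDTP + IDFP + IDFN)."""
    denom = 2 * IDTP + IDFP + IDFN
    if denom == 0:
        raise ValueError("IDF1 undefined for all-zero counts")
    return 100.0 * 2 * IDTP / denom


def evaluate_annotations(
    annotations: FrameAnnotations, iou_gate: float = 0.5
) -> MetricReport:
    """Full CLEAR + Identity report for in-memory annotations."""
    if annotations.total_gt() == 0:
        raise ValueError("ground truth is empty")
    ctp, cfp, cfn, idsw = clear_match(annotations, iou_gate)
    gt_total = annotations.total_gt()
    idtp, idfp, idfn = identity_match(annotations, iou_gate)
    return MetricReport(
        CTP=ctp, CFP=cfp, CFN=cfn, IDSW=idsw,
        MOTA=mota_from_counts(cfn, cfp, idsw, gt_total),
        IDTP=idtp, IDFP=idfp, IDFN=idfn,
        IDF1=idf1_from_counts(idtp, idfp, idfn),
    )


def evaluate(gt_path, pred_path, iou_gate: float = 0.5) -> MetricReport:
    """Evaluate a MOTChallenge prediction file against a ground-truth file."""
    from .mot_io import read_mot

    gt = read_mot(gt_path)
    pred = read_mot(pred_path)
    ann = FrameAnnotations(
        gt={f: [(r.id, r.box) for r in recs] for f, recs in gt.items()},
        pred={f: [(r.id, r.box) for r in recs] for f, recs in pred.items()},
    )
    return evaluate_annotations(ann, iou_gate)
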