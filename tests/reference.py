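"""Independent reference implementations used only as test oracles.

Deliberately share no code with the package: box overlap goes through
shapely polygons, assignments are found by exhaustive enumeration, and the
metric conventions are re-derived from their definitions.  Everything here
is exponential-time and only run on tiny instances.
"""

from __future__ import annotations

import itertools

from shapely.geometry import box as shapely_box


def ref_iou(a: tuple, b: tuple) -> float:
    """IoU of (x, y, w, h) boxes via shapely polygon areas."""
    if a[2] <= 0 or a[3] <= 0 or b[2] <= 0 or b[3] <= 0:
        return 0.0
    pa = shapely_box(a[0], a[1], a[0] + a[2], a[1] + a[3])
    pb = shapely_box(b[0], b[1], b[0] + b[2], b[1] + b[3])
    inter = pa.intersection(pb).area
    union = pa.union(pb).area
    return inter / union if union > 0 else 0.0


def brute_force_associate(boxes_a, boxes_b, gate):
    """Min-total-(1-IoU) complete assignment, then gate — by enumeration.

    Boxes are (x, y, w, h) tuples.  Returns the set of surviving
    (i, j) pairs.
    """
    n, m = len(boxes_a), len(boxes_b)
    k = min(n, m)
    if k == 0:
        return set()
    best_cost, best = None, None
    for rows in itertools.combinations(range(n), k):
        for cols in itertools.permutations(range(m), k):
            cost = sum(1.0 - ref_iou(boxes_a[r], boxes_b[c]) for r, c in zip(rows, cols))
            if best_cost is None or cost < best_cost - 1e-12:
                best_cost, best = cost, list(zip(rows, cols))
    return {
        (r, c)
        for r, c in best
        if ref_iou(boxes_a[r], boxes_b[c]) >= gate and ref_iou(boxes_a[r], boxes_b[c]) > 0
    }


def _best_frame_matching(gt_entries, pred_entries, prev, gate):
    """Kept previous pairs + max-cardinality min-cost gated matching (enumerated)."""
    gt_boxes = dict(gt_entries)
    pred_boxes = dict(pred_entries)
    matches = {}
    for g in gt_boxes:
        p = prev.get(g)
        if p is not None and p in pred_boxes and p not in matches.values():
            v = ref_iou(gt_boxes[g], pred_boxes[p])
            if v >= gate and v > 0:
                matches[g] = p
    rem_g = [g for g in gt_boxes if g not in matches]
    rem_p = [p for p in pred_boxes if p not in matches.values()]
    best_key, best_pairs = None, []
    k = min(len(rem_g), len(rem_p))
    # any gated matching is the gated subset of some complete injection,
    # so enumerating size-k injections suffices
    for gs in itertools.combinations(rem_g, k):
        for ps in itertools.permutations(rem_p, k):
            pairs = [
                (g, p)
                for g, p in zip(gs, ps)
                if ref_iou(gt_boxes[g], pred_boxes[p]) >= gate
                and ref_iou(gt_boxes[g], pred_boxes[p]) > 0
            ]
            cost = sum(1.0 - ref_iou(gt_boxes[g], pred_boxes[p]) for g, p in pairs)
            key = (-len(pairs), cost)
            if best_key is None or key < best_key:
                best_key, best_pairs = key, pairs
    matches.update(dict(best_pairs))
    return matches


def reference_clear(gt, pred, gate=0.5):
    """CLEAR counts (CTP, CFP, CFN, IDSW) by per-frame enumeration.

    gt/pred: {frame: [(identity, (x, y, w, h)), ...]}.
    """
    ctp = cfp = cfn = idsw = 0
    prev, last = {}, {}
    for f in sorted(set(gt) | set(pred)):
        ge = gt.get(f, [])
        pe = pred.get(f, [])
        matches = _best_frame_matching(ge, pe, prev, gate)
        ctp += len(matches)
        cfn += len(ge) - len(matches)
        cfp += len(pe) - len(matches)
        for g, p in matches.items():
            if g in last and last[g] != p:
                idsw += 1
            last[g] = p
        prev = matches
    return ctp, cfp, cfn, idsw


def reference_identity(gt, pred, gate=0.5):
    """(IDTP, IDFP, IDFN) by exhaustive search over identity bijections."""
    gt_len, pred_len, overlap = {}, {}, {}
    for f in sorted(set(gt) | set(pred)):
        for g, bg in gt.get(f, []):
            gt_len[g] = gt_len.get(g, 0) + 1
            for p, bp in pred.get(f, []):
                v = ref_iou(bg, bp)
                if v >= gate and v > 0:
                    overlap[(g, p)] = overlap.get((g, p), 0) + 1
        for p, _ in pred.get(f, []):
            pred_len[p] = pred_len.get(p, 0) + 1
    gids, pids = sorted(gt_len), sorted(pred_len)
    total_gt = sum(gt_len.values())
    total_pred = sum(pred_len.values())
    best_idtp = 0
    k = min(len(gids), len(pids))
    # overlaps are non-negative, so a complete size-k injection always
    # dominates its sub-mappings
    for gs in itertools.combinations(gids, k):
        for ps in itertools.permutations(pids, k):
            idtp = sum(overlap.get((g, p), 0) for g, p in zip(gs, ps))
            best_idtp = max(best_idtp, idtp)
    return best_idtp, total_pred - best_idtp, total_gt - best_idtp
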