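import numpy as np
import pytest

from pigmotion import (
    BBox,
    FlowField,
    MovementRecord,
    MovementSeries,
    Point,
    ObjectSpec,
    SceneConfig,
    bbox_center_movement,
    box_mean_flow_movement,
    cumulative,
    estimate_flow,
    generate_scene,
    per_track_movement,
    propagate_point,
    rep_point_movement,
)
from pigmotion.kalman import kf_initiate
from pigmotion.tracker import Track


def uniform_field(du, dv, h=40, w=40):
    return FlowField(np.full((h, w), float(du)), np.full((h, w), float(dv)))


def make_track(tid, boxes_by_frame):
    first = boxes_by_frame[min(boxes_by_frame)]
    t = Track(track_id=tid, state=kf_initiate(first))
    t.boxes = dict(boxes_by_frame)
    return t


class TestBBoxCenter:
    def test_identical_boxes(self):
        b = BBox(3, 4, 10, 10)
        assert bbox_center_movement(b, b) == 0

    def test_three_four_five(self):
        assert bbox_center_movement(BBox(-5, -5, 10, 10), BBox(-2, -1, 10, 10)) == 5

    def test_jitter_mean_matches_rayleigh(self):
        """Center jitter N(0, s^2 I) per frame gives mean step s*sqrt(pi)."""
        rng = np.random.default_rng(0)
        sigma = 2.0
        base = BBox(50, 50, 20, 20)
        prev = base
        vals = []
        for _ in range(10_000):
            dx, dy = rng.normal(0, sigma, 2)
            cur = BBox(50 + dx, 50 + dy, 20, 20)
            vals.append(bbox_center_movement(prev, cur))
            prev = cur
        # difference of two N(0, s^2) is N(0, 2 s^2); E||.|| = s*sqrt(pi)
        assert np.mean(vals) == pytest.approx(sigma * np.sqrt(np.pi), rel=0.1)
        assert min(vals) > 0


class TestRepPoint:
    def test_uniform_field(self):
        assert rep_point_movement(uniform_field(3, 4), Point(5, 5)) == pytest.approx(5)

    def test_zero_field(self):
        assert rep_point_movement(uniform_field(0, 0), Point(5, 5)) == 0

    def test_diagonal_unit(self):
        assert rep_point_movement(uniform_field(1, -1), Point(2, 2)) == pytest.approx(
            np.sqrt(2)
        )

    def test_propagate(self):
        F = uniform_field(1, -2)
        p = propagate_point(Point(10, 10), F)
        assert (p.px, p.py) == (11, 8)

    def test_propagate_zero_field_fixed_point(self):
        p = propagate_point(Point(7, 3), uniform_field(0, 0))
        assert (p.px, p.py) == (7, 3)

    def test_k_steps_uniform(self):
        F = uniform_field(2, 0)
        p = Point(1, 5)
        for _ in range(5):
            p = propagate_point(p, F)
        assert (p.px, p.py) == (11, 5)


class TestBoxMeanFlow:
    def test_uniform_field_any_box(self):
        assert box_mean_flow_movement(uniform_field(3, 4), BBox(5, 5, 10, 8)) == pytest.approx(5)

    def test_zero_field(self):
        assert box_mean_flow_movement(uniform_field(0, 0), BBox(5, 5, 10, 8)) == 0

    def test_hand_average(self):
        du = np.zeros((4, 4))
        du[0, 0] = 5.0
        du[0, 1] = 5.0
        F = FlowField(du, np.zeros((4, 4)))
        assert box_mean_flow_movement(F, BBox(0, 0, 2, 2)) == pytest.approx(2.5)

    def test_box_outside_frame_rejected(self):
        with pytest.raises(ValueError):
            box_mean_flow_movement(uniform_field(1, 1), BBox(100, 100, 5, 5))

    def test_fill_factor_law(self):
        """Object of area A at speed s in a box of area P -> mean = s*A/P."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            W = H = 60
            bw, bh = rng.integers(10, 30, 2)
            ow, oh = rng.integers(2, bw + 1), rng.integers(2, bh + 1)
            x, y = rng.integers(0, W - bw), rng.integers(0, H - bh)
            s_dx, s_dy = rng.uniform(-4, 4, 2)
            s = float(np.hypot(s_dx, s_dy))
            du = np.zeros((H, W))
            dv = np.zeros((H, W))
            du[y : y + oh, x : x + ow] = s_dx
            dv[y : y + oh, x : x + ow] = s_dy
            got = box_mean_flow_movement(FlowField(du, dv), BBox(x, y, bw, bh))
            # single-precision flow storage bounds the achievable exactness
            assert got == pytest.approx(s * (ow * oh) / (bw * bh), abs=1e-6)


class TestPerTrackMovement:
    def test_static_track_zero_flow(self):
        track = make_track(1, {f: BBox(10, 10, 8, 8) for f in range(10)})
        flows = {f: uniform_field(0, 0) for f in range(9)}
        series = per_track_movement([track], flows, "box_mean_flow")
        assert series.cumulative[1] == [0.0] * 9

    def test_full_box_translation_eq5(self):
        """Box-filling object at (3, 4) px/frame: every value 5, sum 500."""
        flows = {f: uniform_field(3, 4, 600, 600) for f in range(100)}
        track = make_track(
            1, {f: BBox(10 + 3 * f, 10 + 4 * f, 20, 15) for f in range(101)}
        )
        series = per_track_movement([track], flows, "box_mean_flow")
        assert all(r.value == pytest.approx(5.0) for r in series.records[1])
        assert series.total(1) == pytest.approx(500.0)

    def test_jittered_centers_exceed_flow_movement(self):
        """Static animal with box jitter: the center method reads phantom
        movement while the in-box flow method stays at zero."""
        rng = np.random.default_rng(1)
        boxes = {
            f: BBox(50 + rng.normal(0, 2), 50 + rng.normal(0, 2), 20, 20)
            for f in range(101)
        }
        track = make_track(1, boxes)
        flows = {f: uniform_field(0, 0, 200, 200) for f in range(100)}
        center_series = per_track_movement([track], flows, "bbox_center")
        flow_series = per_track_movement([track], flows, "box_mean_flow")
        assert center_series.total(1) > 100
        assert flow_series.total(1) == 0

    def test_rep_point_equals_bbox_center_under_uniform_translation(self):
        flows = {f: uniform_field(2, -1, 100, 100) for f in range(10)}
        boxes = {f: BBox(10 + 2 * f, 30 - f, 12, 10) for f in range(11)}
        track = make_track(3, boxes)
        rp = per_track_movement([track], flows, "rep_point")
        bc = per_track_movement([track], flows, "bbox_center")
        assert rp.cumulative[3] == pytest.approx(bc.cumulative[3])

    def test_track_gap_produces_no_records(self):
        boxes = {0: BBox(0, 0, 5, 5), 1: BBox(1, 0, 5, 5), 5: BBox(5, 0, 5, 5), 6: BBox(6, 0, 5, 5)}
        track = make_track(1, boxes)
        flows = {f: uniform_field(1, 0, 50, 50) for f in range(6)}
        series = per_track_movement([track], flows, "box_mean_flow")
        assert [r.frame for r in series.records[1]] == [0, 5]

    def test_missing_flow_rejected(self):
        track = make_track(1, {0: BBox(0, 0, 5, 5), 1: BBox(1, 0, 5, 5)})
        with pytest.raises(KeyError):
            per_track_movement([track], {}, "box_mean_flow")


class TestSeries:
    def test_cumulative_values(self):
        s = MovementSeries()
        for f, v in enumerate([1.0, 2.0, 3.0]):
            s.add(MovementRecord(1, f, "bbox_center", v))
        assert s.cumulative[1] == [1.0, 3.0, 6.0]
        assert cumulative(s).cumulative[1] == [1.0, 3.0, 6.0]

    def test_non_decreasing_and_conserving(self):
        rng = np.random.default_rng(2)
        s = MovementSeries()
        vals = rng.uniform(0, 5, 50)
        for f, v in enumerate(vals):
            s.add(MovementRecord(2, f, "rep_point", float(v)))
        cum = s.cumulative[2]
        assert all(b >= a for a, b in zip(cum, cum[1:]))
        assert cum[-1] == pytest.approx(vals.sum())

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            MovementRecord(1, 0, "bbox_center", -0.5)


class TestStaticSeparation:
    def test_static_object_bbox_vs_flow_cumulative(self):
        """Core contrast: jittered boxes around a static animal accumulate
        >100 px of phantom center movement over 100 frames; mean in-box
        flow stays at 0 (ground truth) and near 0 (estimated)."""
        spec = ObjectSpec(
            object_id=1, size=(60, 45), shape="rectangle", start=(80, 80),
            velocity=(0.0, 0.0), texture_seed=2,
        )
        cfg = SceneConfig(width=160, height=160, n_frames=101, n_objects=1, master_seed=2)
        frames, gt = generate_scene(cfg, [spec])
        rng = np.random.default_rng(3)
        jittered = {
            f: BBox(b.x + rng.normal(0, 2), b.y + rng.normal(0, 2), b.w, b.h)
            for f, entries in gt.boxes.items()
            for _, b in entries
        }
        track = make_track(1, jittered)
        center_total = per_track_movement([track], {}, "bbox_center").total(1)
        flow_total = per_track_movement([track], gt.flows, "box_mean_flow").total(1)
        est_flows = {
            f: estimate_flow(frames[f], frames[f + 1]) for f in range(0, 100, 10)
        }
        est_vals = [
            box_mean_flow_movement(est_flows[f], jittered[f]) for f in est_flows
        ]
        assert center_total > 100
        assert flow_total == 0
        assert np.mean(est_vals) * 100 < 20  # scaled to the 100-pair budget
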