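"""Synthetic overhead scenes with exact ground truth.

Emulates a fixed overhead pen camera: a static textured floor with a
handful of textured animals (rectangles or ellipses), some stationary and
some drifting at constant velocity, rendered with sub-pixel bilinear
splatting.  The generator emits, per frame, the images, amodal ground-truth
boxes with identities and, per frame pair, the exact per-pixel flow (object
pixels carry the object's displacement, background is exactly zero, and
occluding objects win by draw order).  A detection-noise model turns the
ground truth into realistic detector output: box jitter and size change
around static animals, dropped boxes, low confidence when an animal is
mostly occluded, and spurious boxes.

Textures are seeded band-limited noise (smoothed white noise), which gives
the gradient structure classical brightness-constancy flow estimation
needs; flat shapes would be aperture-degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .flow import FlowField
from .geometry import BBox, Detection

__all__ = [
    "ObjectSpec",
    "SceneConfig",
    "DetectionNoise",
    "GroundTruth",
    "generate_scene",
    "perturb_detections",
    "decimate_frames",
]


@dataclass
class ObjectSpec:
    """One scene object: shape, size, motion program and texture seed.

    Either ``positions`` (explicit per-frame centers) or ``start`` plus
    ``velocity`` (constant drift, reflected at the frame borders) defines
    the trajectory.  ``shape_change`` optionally scales the size per frame,
    modelling the box-deformation failure mode around stationary animals.
    """

    object_id: int
    size: tuple[float, float]  # (w, h) pixels
    shape: str = "rectangle"  # or "ellipse"
    start: tuple[float, float] | None = None  # center at frame 0
    velocity: tuple[float, float] = (0.0, 0.0)  # pixels/frame
    positions: list[tuple[float, float]] | None = None
    texture_seed: int = 0
    shape_change: list[float] | None = None

    def centers(self, n_frames: int, width: float, height: float) -> list[tuple[float, float]]:
        if self.positions is not None:
            if len(self.positions) < n_frames:
                raise ValueError("explicit trajectory shorter than the scene")
            return list(self.positions[:n_frames])
        if self.start is None:
            raise ValueError("object needs either positions or a start point")
        w, h = self.size
        cx, cy = self.start
        vx, vy = self.velocity
        # keep at least half the object inside; reflect velocity at borders
        out = []
        for _ in range(n_frames):
            out.append((cx, cy))
            cx, cy = cx + vx, cy + vy
            if cx < w / 4 or cx > width - w / 4:
                vx = -vx
                cx = float(np.clip(cx, w / 4, width - w / 4))
            if cy < h / 4 or cy > height - h / 4:
                vy = -vy
                cy = float(np.clip(cy, h / 4, height - h / 4))
        return out


@dataclass
class DetectionNoise:
    """Detector imperfection model (all defaults deliberately mild)."""

    center_jitter_sigma: float = 0.0  # px, per-axis Gaussian on the center
    size_jitter_sigma: float = 0.0  # px, per-axis Gaussian on (w, h)
    miss_rate: float = 0.0  # probability a true box is dropped
    spurious_rate: float = 0.0  # expected false boxes per frame (Poisson)
    occlusion_score_drop: float = 0.3  # score when visible fraction < 0.5
    base_score: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_rate <= 1.0):
            raise ValueError("miss_rate must be a probability")
        if self.center_jitter_sigma < 0 or self.size_jitter_sigma < 0:
            raise ValueError("jitter sigmas must be >= 0")
        for s in (self.occlusion_score_drop, self.base_score):
            if not (0.0 <= s <= 1.0):
                raise ValueError("scores must be in [0, 1]")


@dataclass
class SceneConfig:
    """Scene layout: frame geometry, duration, population and seeds."""

    width: int = 640
    height: int = 640
    n_frames: int = 50
    fps: float = 15.0  # metadata only; movement is reported per frame
    n_objects: int = 6
    background_texture_seed: int = 0
    master_seed: int = 0
    noise: DetectionNoise = field(default_factory=DetectionNoise)

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("a scene needs at least 2 frames")
        if self.width < 16 or self.height < 16:
            raise ValueError("frame too small")


@dataclass
class GroundTruth:
    """Exact per-frame annotations emitted alongside the rendered frames."""

    boxes: dict[int, list[tuple[int, BBox]]]  # frame -> [(identity, box)]
    flows: dict[int, FlowField]  # frame t -> flow into t+1
    displacements: dict[int, list[tuple[float, float]]]  # id -> per-pair (dx, dy)
    visible_fraction: dict[int, dict[int, float]]  # frame -> id -> fraction

    def detections(self, base_score: float = 1.0) -> dict[int, list[Detection]]:
        """Noise-free detections straight from the ground-truth boxes."""
        return {
            f: [Detection(box=b, score=base_score, frame=f) for _, b in entries]
            for f, entries in self.boxes.items()
        }


def _texture(shape: tuple[int, int], seed: int, lo: float, hi: float,
             smooth: float = 1.2) -> np.ndarray:
    rng = np.random.default_rng(seed)
    t = ndimage.gaussian_filter(rng.standard_normal(shape), smooth, mode="wrap")
    t = (t - t.min()) / max(t.max() - t.min(), 1e-9)
    return lo + (hi - lo) * t


def _object_patch(spec: ObjectSpec, w: float, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Texture patch and soft mask at integer size (+1 px splat margin)."""
    pw, ph = int(np.ceil(w)) + 1, int(np.ceil(h)) + 1
    tex = _texture((ph, pw), spec.texture_seed + 7919, 0.45, 1.0, smooth=1.0)
    yy, xx = np.mgrid[0:ph, 0:pw]
    if spec.shape == "ellipse":
        mask = (
            ((xx + 0.5 - pw / 2) / (w / 2)) ** 2
            + ((yy + 0.5 - ph / 2) / (h / 2)) ** 2
        ) <= 1.0
        mask = mask.astype(float)
    elif spec.shape == "rectangle":
        # exact per-pixel coverage of [0, w) x [0, h), fractional at edges
        mask = np.clip(w - xx, 0, 1) * np.clip(h - yy, 0, 1)
    else:
        raise ValueError(f"unknown shape {spec.shape!r}")
    return tex, mask


def _splat(frame, flow_pair, tex, mask, tl_x, tl_y, disp, zbuf, oid):
    """Bilinearly splat a patch at sub-pixel top-left (tl_x, tl_y)."""
    H, W = frame.shape
    bx, by = int(np.floor(tl_x)), int(np.floor(tl_y))
    fx, fy = tl_x - bx, tl_y - by
    # shift patch and mask by the fractional offset (order-1 = bilinear)
    if fx or fy:
        tex = ndimage.shift(tex, (fy, fx), order=1, mode="nearest")
        mask = ndimage.shift(mask, (fy, fx), order=1, mode="constant", cval=0.0)
    ph, pw = tex.shape
    x0, x1 = max(bx, 0), min(bx + pw, W)
    y0, y1 = max(by, 0), min(by + ph, H)
    if x0 >= x1 or y0 >= y1:
        raise ValueError(f"object {oid} left the frame entirely")
    sx, sy = x0 - bx, y0 - by
    m = mask[sy:sy + (y1 - y0), sx:sx + (x1 - x0)]
    t = tex[sy:sy + (y1 - y0), sx:sx + (x1 - x0)]
    region = frame[y0:y1, x0:x1]
    frame[y0:y1, x0:x1] = region * (1 - m) + t * m
    hard = m > 0.5
    if flow_pair is not None:
        flow_pair[0][y0:y1, x0:x1][hard] = disp[0]
        flow_pair[1][y0:y1, x0:x1][hard] = disp[1]
    zbuf[y0:y1, x0:x1][hard] = oid


def _default_objects(config: SceneConfig) -> list[ObjectSpec]:
    """Random population: one guaranteed static animal, the rest drifting.

    The frame is divided into a grid of territories, one animal bouncing
    inside each, so distinct animals' boxes never overlap.  Deliberate
    occlusion scenes come from :func:`crossing_objects` or hand-built
    specs instead.
    """
    rng = np.random.default_rng(config.master_seed + 1)
    W, H = config.width, config.height
    rows = int(np.ceil(np.sqrt(config.n_objects)))
    cols = int(np.ceil(config.n_objects / rows))
    cell_w, cell_h = W / cols, H / rows
    specs: list[ObjectSpec] = []
    for k in range(config.n_objects):
        r, c = divmod(k, cols)
        w = rng.uniform(0.35, 0.5) * cell_w
        h = rng.uniform(0.30, 0.45) * cell_h
        x_lo, x_hi = c * cell_w + w / 2 + 1, (c + 1) * cell_w - w / 2 - 1
        y_lo, y_hi = r * cell_h + h / 2 + 1, (r + 1) * cell_h - h / 2 - 1
        cx = rng.uniform(x_lo, x_hi)
        cy = rng.uniform(y_lo, y_hi)
        if k == 0:
            vx = vy = 0.0
        else:
            speed = rng.uniform(0.5, 3.0)
            ang = rng.uniform(0, 2 * np.pi)
            vx, vy = speed * np.cos(ang), speed * np.sin(ang)
        positions = []
        for _ in range(config.n_frames):
            positions.append((cx, cy))
            cx, cy = cx + vx, cy + vy
            if not (x_lo <= cx <= x_hi):
                vx = -vx
                cx = float(np.clip(cx, x_lo, x_hi))
            if not (y_lo <= cy <= y_hi):
                vy = -vy
                cy = float(np.clip(cy, y_lo, y_hi))
        specs.append(
            ObjectSpec(
                object_id=k + 1,
                size=(w, h),
                shape="ellipse" if rng.random() < 0.5 else "rectangle",
                positions=positions,
                texture_seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def crossing_objects(config: SceneConfig) -> list[ObjectSpec]:
    """Territory population plus one small animal crossing under a larger one.

    The crossing animal (listed first, so it is the one occluded) passes
    beneath the static animal of territory 0: its visible fraction drops
    below one half mid-sequence while the two boxes' IoU stays well under
    0.5, because the occluded animal is much smaller.  This exercises
    occlusion score drops and second-stage association without making
    distinct animals' detections NMS-ambiguous.
    """
    specs = _default_objects(config)
    big = specs[0]
    bx, by = big.positions[0]
    w = big.size[0] * 0.55
    h = big.size[1] * 0.55
    # shuttle back and forth across territory 0 at fixed height
    rows = int(np.ceil(np.sqrt(config.n_objects)))
    cols = int(np.ceil(config.n_objects / rows))
    cell_w = config.width / cols
    x_lo, x_hi = w / 2 + 1, cell_w - w / 2 - 1
    positions = []
    cx, vx = x_lo, 2.5
    for _ in range(config.n_frames):
        positions.append((cx, by))
        cx += vx
        if not (x_lo <= cx <= x_hi):
            vx = -vx
            cx = float(np.clip(cx, x_lo, x_hi))
    crosser = ObjectSpec(
        object_id=max(s.object_id for s in specs) + 1,
        size=(w, h),
        shape="rectangle",
        positions=positions,
        texture_seed=int(np.random.default_rng(config.master_seed + 99).integers(2**31 - 1)),
    )
    # listed first: everything later in the list occludes it
    return [crosser] + specs


def generate_scene(
    config: SceneConfig, objects: list[ObjectSpec] | None = None
) -> tuple[list[np.ndarray], GroundTruth]:
    """Render the scene; fully determined by the config's seeds.

    Returns (frames, ground truth).  Frames are float grayscale in [0, 1].
    Later-listed objects occlude earlier ones.
    """
    if objects is None:
        objects = _default_objects(config)
    ids = [o.object_id for o in objects]
    if len(ids) != len(set(ids)):
        raise ValueError("object ids must be unique")
    W, H, n = config.width, config.height, config.n_frames
    background = _texture((H, W), config.background_texture_seed + 13, 0.05, 0.45)
    trajectories = {o.object_id: o.centers(n, W, H) for o in objects}

    frames: list[np.ndarray] = []
    boxes: dict[int, list[tuple[int, BBox]]] = {}
    flows: dict[int, FlowField] = {}
    displacements: dict[int, list[tuple[float, float]]] = {
        o.object_id: [] for o in objects
    }
    visible: dict[int, dict[int, float]] = {}

    base_patches = {o.object_id: _object_patch(o, *o.size) for o in objects}

    for f in range(n):
        frame = background.copy()
        zbuf = np.zeros((H, W), dtype=np.int32)
        flow_pair = (
            (np.zeros((H, W)), np.zeros((H, W))) if f < n - 1 else None
        )
        boxes[f] = []
        for o in objects:
            cx, cy = trajectories[o.object_id][f]
            mult = 1.0
            if o.shape_change is not None:
                mult = o.shape_change[min(f, len(o.shape_change) - 1)]
            w, h = o.size[0] * mult, o.size[1] * mult
            tex, mask = base_patches[o.object_id]
            if mult != 1.0:
                tex, mask = _object_patch(o, w, h)
            tl_x, tl_y = cx - w / 2, cy - h / 2
            if f < n - 1:
                nx, ny = trajectories[o.object_id][f + 1]
                disp = (nx - cx, ny - cy)
                displacements[o.object_id].append(disp)
            else:
                disp = (0.0, 0.0)
            _splat(
                frame,
                flow_pair,
                tex,
                mask,
                tl_x,
                tl_y,
                disp,
                zbuf,
                o.object_id,
            )
            boxes[f].append((o.object_id, BBox(tl_x, tl_y, w, h)))
        # visible fraction from the z-buffer (amodal area as denominator)
        visible[f] = {}
        for o in objects:
            _, b = next(e for e in boxes[f] if e[0] == o.object_id)
            mask_area = max(np.count_nonzero(base_patches[o.object_id][1] > 0.5), 1)
            if o.shape_change is not None:
                mult = o.shape_change[min(f, len(o.shape_change) - 1)]
                mask_area = max(int(mask_area * mult * mult), 1)
            visible[f][o.object_id] = float(
                np.count_nonzero(zbuf == o.object_id) / mask_area
            )
        if flow_pair is not None:
            flows[f] = FlowField(flow_pair[0], flow_pair[1])
        frames.append(frame)

    return frames, GroundTruth(boxes, flows, displacements, visible)


def perturb_detections(
    gt: GroundTruth, noise: DetectionNoise, seed: int
) -> dict[int, list[Detection]]:
    """Noisy detector output derived from the ground truth.

    Per true box: dropped with ``miss_rate``, else center and size get
    independent zero-mean Gaussian jitter; the score is ``base_score``
    unless the object's visible fraction is below one half, in which case
    the occlusion score applies.  Spurious low-score boxes arrive as a
    Poisson process uniform over the frame.
    """
    rng = np.random.default_rng(seed)
    out: dict[int, list[Detection]] = {}
    frames = sorted(gt.boxes)
    # frame extent inferred from flow fields when present, else from boxes
    if gt.flows:
        anyf = next(iter(gt.flows.values()))
        W, H = anyf.width, anyf.height
    else:
        W = max(b.right for entries in gt.boxes.values() for _, b in entries)
        H = max(b.bottom for entries in gt.boxes.values() for _, b in entries)
    for f in frames:
        dets: list[Detection] = []
        for oid, box in gt.boxes[f]:
            if rng.random() < noise.miss_rate:
                continue
            cx = box.x + box.w / 2 + rng.normal(0, noise.center_jitter_sigma)
            cy = box.y + box.h / 2 + rng.normal(0, noise.center_jitter_sigma)
            w = max(box.w + rng.normal(0, noise.size_jitter_sigma), 2.0)
            h = max(box.h + rng.normal(0, noise.size_jitter_sigma), 2.0)
            vis = gt.visible_fraction.get(f, {}).get(oid, 1.0)
            score = noise.occlusion_score_drop if vis < 0.5 else noise.base_score
            dets.append(
                Detection(box=BBox(cx - w / 2, cy - h / 2, w, h), score=score, frame=f)
            )
        for _ in range(rng.poisson(noise.spurious_rate)):
            w = rng.uniform(8, 0.15 * W)
            h = rng.uniform(8, 0.15 * H)
            x = rng.uniform(0, W - w)
            y = rng.uniform(0, H - h)
            score = rng.uniform(0.1, 0.45)
            dets.append(Detection(box=BBox(x, y, w, h), score=score, frame=f))
        out[f] = dets
    return out


def decimate_frames(n_source_frames: int, src_fps: float, dst_fps: float) -> list[int]:
    """Indices retained when reducing the frame rate (every k-th frame).

    ``src_fps`` must be an integer multiple of ``dst_fps``.
    """
    if src_fps <= 0 or dst_fps <= 0:
        raise ValueError("frame rates must be positive")
    ratio = src_fps / dst_fps
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"{src_fps} fps is not an integer multiple of {dst_fps} fps")
    step = int(round(ratio))
    return list(range(0, n_source_frames, step))
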