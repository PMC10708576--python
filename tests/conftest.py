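from __future__ import annotations

import numpy as np
import pytest

from pigmotion import BBox, SceneConfig, generate_scene


def random_box(rng: np.random.Generator, span: float = 100.0) -> BBox:
    return BBox(
        rng.uniform(0, span),
        rng.uniform(0, span),
        rng.uniform(1, span / 2),
        rng.uniform(1, span / 2),
    )


def random_mot_scenario(rng: np.random.Generator, n_ids=4, n_frames=20):
    """Random GT tracks plus a degraded copy as predictions.

    Returns (gt, pred) as {frame: [(identity, (x, y, w, h)), ...]} with box
    jitter, occasional drops, identity relabels, and spurious predictions.
    """
    gt: dict[int, list] = {f: [] for f in range(n_frames)}
    pred: dict[int, list] = {f: [] for f in range(n_frames)}
    for gid in range(1, n_ids + 1):
        x, y = rng.uniform(0, 150, size=2)
        w, h = rng.uniform(15, 40, size=2)
        vx, vy = rng.uniform(-2, 2, size=2)
        pid = gid + 100
        switch_at = (
            n_frames + 1
            if rng.random() > 0.4 or n_frames <= 3
            else int(rng.integers(3, n_frames))
        )
        for f in range(n_frames):
            if rng.random() < 0.1:  # GT object absent this frame
                x, y = x + vx, y + vy
                continue
            gt[f].append((gid, (x, y, w, h)))
            if rng.random() >= 0.15:  # prediction present
                jx, jy = rng.normal(0, 1.5, size=2)
                this_pid = pid if f < switch_at else pid + 1000
                pred[f].append((this_pid, (x + jx, y + jy, w, h)))
            x, y = x + vx, y + vy
    for f in range(n_frames):
        if rng.random() < 0.2:  # spurious prediction far from everything
            pred[f].append(
                (9000 + f % 3, (rng.uniform(300, 400), rng.uniform(300, 400), 20, 20))
            )
    return gt, pred


@pytest.fixture(scope="session")
def small_scene():
    """A 5-object 60-frame scene shared by read-only tests."""
    cfg = SceneConfig(width=320, height=320, n_frames=60, n_objects=5, master_seed=7)
    frames, gt = generate_scene(cfg)
    return cfg, frames, gt
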