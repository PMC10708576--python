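"""Dense optical flow: estimation, file I/O, and visualization.

The estimator solves the brightness-constancy model
``I(x, y, t) = I(x + dx, y + dy, t + 1)`` with a coarse-to-fine pyramidal
iterative Lucas--Kanade scheme: at each pyramid level the current flow warps
the second frame toward the first, and a Gaussian-weighted local
least-squares solve on the spatial/temporal gradients yields an increment.
The convention is *forward* flow: ``F`` at pixel (x, y) of frame t is the
displacement of that pixel into frame t+1, in pixels/frame.

Any other provider of per-pixel (dx, dy) fields — e.g. precomputed
Middlebury ``.flo`` files — can be substituted downstream; every consumer
only sees :class:`FlowField`.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import Point

__all__ = [
    "FlowField",
    "FlowBackendConfig",
    "estimate_flow",
    "flow_at",
    "read_flo",
    "write_flo",
    "flow_to_color",
    "flow_to_arrows",
]

_FLO_MAGIC = 202021.25


@dataclass
class FlowField:
    """Per-pixel displacement field: du = dx, dv = dy, both H x W."""

    du: np.ndarray
    dv: np.ndarray

    def __post_init__(self) -> None:
        self.du = np.asarray(self.du, dtype=np.float32)
        self.dv = np.asarray(self.dv, dtype=np.float32)
        if self.du.shape != self.dv.shape or self.du.ndim != 2:
            raise ValueError("du and dv must be 2-D arrays of identical shape")
        if not (np.isfinite(self.du).all() and np.isfinite(self.dv).all()):
            raise ValueError("flow values must be finite")

    @property
    def height(self) -> int:
        return self.du.shape[0]

    @property
    def width(self) -> int:
        return self.du.shape[1]

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.du, self.dv)


@dataclass
class FlowBackendConfig:
    """Parameters of the built-in pyramidal Lucas--Kanade estimator.

    window is the side of the Gaussian-weighted aggregation window in
    pixels (odd, >= 3); iterations is the number of warp/solve refinements
    per pyramid level.
    """

    pyramid_levels: int = 3
    pyramid_scale: float = 0.5
    window: int = 15
    iterations: int = 3

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if not (0.0 < self.pyramid_scale < 1.0):
            raise ValueError("pyramid_scale must be in (0, 1)")
        if self.pyramid_levels < 1 or self.iterations < 1:
            raise ValueError("pyramid_levels and iterations must be >= 1")


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=2)  # luminance average
    if img.ndim != 2:
        raise ValueError("frames must be 2-D grayscale or H x W x C color")
    return img


def _warp(img: np.ndarray, du: np.ndarray, dv: np.ndarray) -> np.ndarray:
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    return ndimage.map_coordinates(
        img, [yy + dv, xx + du], order=1, mode="nearest"
    )


def _lk_refine(
    I0: np.ndarray, I1: np.ndarray, du: np.ndarray, dv: np.ndarray,
    window: int, iterations: int,
) -> tuple[np.ndarray, np.ndarray]:
    sigma = window / 5.0
    # regularizer keeps textureless regions finite and near zero
    gy0, gx0 = np.gradient(I0)
    lam = 1e-4 * float(np.mean(gx0**2 + gy0**2)) + 1e-8
    step_cap = float(window)
    for _ in range(iterations):
        I1w = _warp(I1, du, dv)
        gy1, gx1 = np.gradient(I1w)
        Ix = 0.5 * (gx0 + gx1)
        Iy = 0.5 * (gy0 + gy1)
        It = I1w - I0

        def agg(a: np.ndarray) -> np.ndarray:
            return ndimage.gaussian_filter(a, sigma, mode="nearest")

        A11 = agg(Ix * Ix) + lam
        A12 = agg(Ix * Iy)
        A22 = agg(Iy * Iy) + lam
        b1 = agg(Ix * It)
        b2 = agg(Iy * It)
        det = A11 * A22 - A12 * A12
        inc_u = -(A22 * b1 - A12 * b2) / det
        inc_v = -(A11 * b2 - A12 * b1) / det
        np.clip(inc_u, -step_cap, step_cap, out=inc_u)
        np.clip(inc_v, -step_cap, step_cap, out=inc_v)
        du = du + inc_u
        dv = dv + inc_v
    return du, dv


def estimate_flow(
    frame_t: np.ndarray,
    frame_t1: np.ndarray,
    config: FlowBackendConfig | None = None,
) -> FlowField:
    """Dense forward flow from ``frame_t`` to ``frame_t1``.

    Color inputs are reduced to luminance first.  Output shape equals the
    frame shape; borders use replicate padding and are the least reliable
    region (assert properties on the interior).
    """
    config = config or FlowBackendConfig()
    I0 = _to_gray(frame_t)
    I1 = _to_gray(frame_t1)
    if I0.shape != I1.shape:
        raise ValueError(f"frame shapes differ: {I0.shape} vs {I1.shape}")
    # normalize intensities so the regularizer scale is image-independent
    scale = max(I0.max() - I0.min(), 1e-6)
    I0 = (I0 - I0.min()) / scale
    I1 = (I1 - I1.min()) / scale

    # build pyramid, coarsest last; levels that would undershoot the window
    # are dropped
    pyr0, pyr1 = [I0], [I1]
    for _ in range(config.pyramid_levels - 1):
        nh = int(round(pyr0[-1].shape[0] * config.pyramid_scale))
        nw = int(round(pyr0[-1].shape[1] * config.pyramid_scale))
        if min(nh, nw) < config.window:
            break
        pyr0.append(_downsample(pyr0[-1], (nh, nw)))
        pyr1.append(_downsample(pyr1[-1], (nh, nw)))

    du = np.zeros(pyr0[-1].shape)
    dv = np.zeros(pyr0[-1].shape)
    for level in range(len(pyr0) - 1, -1, -1):
        if level < len(pyr0) - 1:
            h, w = pyr0[level].shape
            fy = h / du.shape[0]
            fx = w / du.shape[1]
            du = _resize(du, (h, w)) * fx
            dv = _resize(dv, (h, w)) * fy
        du, dv = _lk_refine(
            pyr0[level], pyr1[level], du, dv, config.window, config.iterations
        )
    return FlowField(du.astype(np.float32), dv.astype(np.float32))


def _downsample(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    smoothed = ndimage.gaussian_filter(img, 1.0, mode="nearest")
    return _resize(smoothed, shape)


def _resize(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    zy = shape[0] / img.shape[0]
    zx = shape[1] / img.shape[1]
    return ndimage.zoom(img, (zy, zx), order=1, mode="nearest", grid_mode=True)


def flow_at(F: FlowField, p: Point) -> tuple[float, float]:
    """Bilinear interpolation of the field at a sub-pixel point."""
    if not (0.0 <= p.px <= F.width - 1 and 0.0 <= p.py <= F.height - 1):
        raise ValueError(
            f"point ({p.px}, {p.py}) outside field {F.width}x{F.height}"
        )
    x0 = int(np.floor(p.px))
    y0 = int(np.floor(p.py))
    x1 = min(x0 + 1, F.width - 1)
    y1 = min(y0 + 1, F.height - 1)
    fx = p.px - x0
    fy = p.py - y0
    w00 = (1 - fx) * (1 - fy)
    w10 = fx * (1 - fy)
    w01 = (1 - fx) * fy
    w11 = fx * fy

    def interp(g: np.ndarray) -> float:
        return float(
            w00 * g[y0, x0] + w10 * g[y0, x1] + w01 * g[y1, x0] + w11 * g[y1, x1]
        )

    return interp(F.du), interp(F.dv)


def write_flo(F: FlowField, path: str | Path) -> None:
    """Write Middlebury ``.flo``: magic, int32 W, int32 H, interleaved f32."""
    with open(path, "wb") as fh:
        fh.write(struct.pack("<f", _FLO_MAGIC))
        fh.write(struct.pack("<ii", F.width, F.height))
        interleaved = np.empty((F.height, F.width, 2), dtype="<f4")
        interleaved[..., 0] = F.du
        interleaved[..., 1] = F.dv
        fh.write(interleaved.tobytes())


def read_flo(path: str | Path) -> FlowField:
    """Read a Middlebury ``.flo`` file; bit-exact inverse of :func:`write_flo`."""
    raw = Path(path).read_bytes()
    if len(raw) < 12:
        raise ValueError(f"{path}: truncated .flo file (header incomplete)")
    (magic,) = struct.unpack_from("<f", raw, 0)
    if abs(magic - _FLO_MAGIC) > 1e-3:
        raise ValueError(f"{path}: bad .flo magic {magic!r}")
    width, height = struct.unpack_from("<ii", raw, 4)
    expected = 12 + 8 * width * height
    if len(raw) != expected:
        raise ValueError(
            f"{path}: size {len(raw)} does not match {width}x{height} field"
        )
    data = np.frombuffer(raw, dtype="<f4", offset=12).reshape(height, width, 2)
    return FlowField(data[..., 0].copy(), data[..., 1].copy())


def flow_to_color(F: FlowField, max_magnitude: float | None = None) -> np.ndarray:
    """Dense color coding: hue = direction, saturation = magnitude.

    Zero flow maps to white.  ``max_magnitude`` fixes the normalization so
    frames can be compared; by default the field's own maximum is used.
    """
    from matplotlib.colors import hsv_to_rgb

    mag = F.magnitude()
    cap = max_magnitude if max_magnitude is not None else float(mag.max())
    if cap <= 0:
        cap = 1.0
    hue = (np.arctan2(F.dv, F.du) + np.pi) / (2 * np.pi)
    sat = np.clip(mag / cap, 0.0, 1.0)
    val = np.ones_like(sat)
    rgb = hsv_to_rgb(np.stack([hue, sat, val], axis=-1))
    return (rgb * 255).astype(np.uint8)


def flow_to_arrows(
    F: FlowField,
    base_image: np.ndarray | None = None,
    stride: int = 16,
    scale: float = 1.0,
    color: tuple[int, int, int] = (255, 0, 0),
) -> np.ndarray:
    """Sparse arrow plot: one arrow per stride x stride cell.

    Arrows start at cell centers and run along the local (du, dv), length
    proportional to magnitude.  Returns an RGB uint8 image.
    """
    from skimage.draw import line as draw_line

    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, w = F.du.shape
    if base_image is None:
        canvas = np.zeros((h, w, 3), dtype=np.uint8)
    else:
        img = np.asarray(base_image)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        canvas = img.astype(np.uint8).copy()
    n_rows = -(-h // stride)
    n_cols = -(-w // stride)
    for cy in (min(i * stride + stride // 2, h - 1) for i in range(n_rows)):
        for cx in (min(j * stride + stride // 2, w - 1) for j in range(n_cols)):
            dx = float(F.du[cy, cx]) * scale
            dy = float(F.dv[cy, cx]) * scale
            ex = int(round(np.clip(cx + dx, 0, w - 1)))
            ey = int(round(np.clip(cy + dy, 0, h - 1)))
            rr, cc = draw_line(cy, cx, ey, ex)
            canvas[rr, cc] = color
    return canvas
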