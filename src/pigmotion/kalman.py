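"""Constant-velocity Kalman filter over box state, SORT/ByteTrack convention.

State is the 8-vector ``(cx, cy, a, h, vcx, vcy, va, vh)`` — box center in
pixels, aspect ratio w/h, height in pixels, and their per-frame velocities.
The measurement is ``(cx, cy, a, h)``.  Process and measurement noise
standard deviations scale with the box height (weights 1/20 for position
terms, 1/160 for velocity terms), which keeps the filter well conditioned
across animal sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BBox

_STD_WEIGHT_POSITION = 1.0 / 20.0
_STD_WEIGHT_VELOCITY = 1.0 / 160.0

# constant-velocity transition and observation matrices
_F = np.eye(8)
_F[:4, 4:] = np.eye(4)
_H = np.eye(4, 8)


@dataclass
class KalmanState:
    """Gaussian belief over the 8-dim box state."""

    mean: np.ndarray  # shape (8,)
    covariance: np.ndarray  # shape (8, 8), symmetric PSD

    def to_box(self) -> BBox:
        cx, cy, a, h = self.mean[:4]
        h = max(h, 0.0)
        w = max(a * h, 0.0)
        return BBox(cx - w / 2.0, cy - h / 2.0, w, h)


def _measurement(box: BBox) -> np.ndarray:
    if box.area <= 0:
        raise ValueError("Kalman measurement requires a positive-area box")
    return np.array(
        [box.x + box.w / 2.0, box.y + box.h / 2.0, box.w / box.h, box.h]
    )


def kf_initiate(box: BBox) -> KalmanState:
    """Start a track belief from a first detection (velocities zero)."""
    z = _measurement(box)
    mean = np.zeros(8)
    mean[:4] = z
    h = box.h
    std = np.array(
        [
            2 * _STD_WEIGHT_POSITION * h,
            2 * _STD_WEIGHT_POSITION * h,
            1e-2,
            2 * _STD_WEIGHT_POSITION * h,
            10 * _STD_WEIGHT_VELOCITY * h,
            10 * _STD_WEIGHT_VELOCITY * h,
            1e-5,
            10 * _STD_WEIGHT_VELOCITY * h,
        ]
    )
    return KalmanState(mean, np.diag(std**2))


def kf_predict(state: KalmanState) -> KalmanState:
    """Propagate one frame under the constant-velocity model."""
    h = max(state.mean[3], 1e-3)
    std = np.array(
        [
            _STD_WEIGHT_POSITION * h,
            _STD_WEIGHT_POSITION * h,
            1e-2,
            _STD_WEIGHT_POSITION * h,
            _STD_WEIGHT_VELOCITY * h,
            _STD_WEIGHT_VELOCITY * h,
            1e-5,
            _STD_WEIGHT_VELOCITY * h,
        ]
    )
    Q = np.diag(std**2)
    mean = _F @ state.mean
    cov = _F @ state.covariance @ _F.T + Q
    return KalmanState(mean, cov)


def kf_update(state: KalmanState, box: BBox) -> KalmanState:
    """Linear-Gaussian correction toward a measured box."""
    z = _measurement(box)
    h = max(state.mean[3], 1e-3)
    std = np.array(
        [
            _STD_WEIGHT_POSITION * h,
            _STD_WEIGHT_POSITION * h,
            1e-1,
            _STD_WEIGHT_POSITION * h,
        ]
    )
    R = np.diag(std**2)
    S = _H @ state.covariance @ _H.T + R
    K = np.linalg.solve(S.T, (_H @ state.covariance.T)).T  # Kalman gain, (8,4)
    innovation = z - _H @ state.mean
    mean = state.mean + K @ innovation
    cov = state.covariance - K @ S @ K.T
    cov = (cov + cov.T) / 2.0  # enforce symmetry against round-off
    return KalmanState(mean, cov)
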