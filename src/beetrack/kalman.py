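"""Constant-velocity Kalman filter over box center, area, and aspect ratio.

State ``x = (u, v, s, r, du, dv, ds)``: box center column/row in pixels,
box area in px^2, aspect ratio w/h (held constant between updates), and the
per-frame velocities of ``u, v, s``.  The observation picks ``(u, v, s, r)``
directly from a detection's bounding box, so both models are linear and the
standard Kalman recursion applies exactly.  Covariance defaults follow the
simple-online-realtime-tracking convention: large initial uncertainty on
the unobserved velocities, small process noise on the area velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .geometry import BBox

__all__ = [
    "KalmanParams",
    "KalmanState",
    "state_from_bbox",
    "bbox_from_state",
    "measurement_from_bbox",
    "kf_predict",
    "kf_update",
]

_DIM_X, _DIM_Z = 7, 4

_F = np.eye(_DIM_X)
_F[0, 4] = _F[1, 5] = _F[2, 6] = 1.0

_H = np.zeros((_DIM_Z, _DIM_X))
_H[0, 0] = _H[1, 1] = _H[2, 2] = _H[3, 3] = 1.0


@dataclass(frozen=True)
class KalmanParams:
    """Noise covariances, all diagonal; units follow the state components."""

    meas_var_center: float = 1.0       # px^2 on u, v
    meas_var_size: float = 10.0        # on s (px^4) and r
    init_var_observed: float = 10.0    # initial variance on u, v, s, r
    init_var_velocity: float = 1.0e4   # initial variance on du, dv, ds
    proc_var_observed: float = 1.0     # per-step process noise on u, v, s, r
    proc_var_velocity: float = 0.01    # per-step process noise on du, dv
    proc_var_area_velocity: float = 1.0e-4  # per-step process noise on ds

    def R(self) -> np.ndarray:
        return np.diag([self.meas_var_center, self.meas_var_center,
                        self.meas_var_size, self.meas_var_size])

    def Q(self) -> np.ndarray:
        return np.diag([self.proc_var_observed] * 4
                       + [self.proc_var_velocity] * 2
                       + [self.proc_var_area_velocity])

    def P0(self) -> np.ndarray:
        return np.diag([self.init_var_observed] * 4 + [self.init_var_velocity] * 3)


@dataclass
class KalmanState:
    """Filter mean ``x`` (7,) and covariance ``P`` (7, 7)."""

    x: np.ndarray
    P: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float).reshape(_DIM_X)
        self.P = np.asarray(self.P, dtype=float).reshape(_DIM_X, _DIM_X)


def measurement_from_bbox(b: BBox) -> np.ndarray:
    """Observation vector ``z = (u, v, s, r)`` from a box."""
    u, v = b.center
    return np.array([u, v, b.w * b.h, b.w / b.h], dtype=float)


def state_from_bbox(b: BBox, params: KalmanParams | None = None) -> KalmanState:
    """Initialize a track state from its first detection: zero velocities,
    large velocity uncertainty."""
    params = params or KalmanParams()
    x = np.zeros(_DIM_X)
    x[:4] = measurement_from_bbox(b)
    return KalmanState(x, params.P0())


def bbox_from_state(state: KalmanState | np.ndarray) -> BBox:
    """Box implied by the state mean; requires positive area and aspect ratio."""
    x = state.x if isinstance(state, KalmanState) else np.asarray(state, dtype=float)
    u, v, s, r = x[:4]
    if s <= 0 or r <= 0:
        raise ValidationError(f"state has non-positive area/aspect: s={s}, r={r}")
    w = np.sqrt(s * r)
    h = s / w
    return BBox(u - w / 2.0, v - h / 2.0, w, h)


def _symmetrize(P: np.ndarray) -> np.ndarray:
    return (P + P.T) / 2.0


def kf_predict(state: KalmanState, params: KalmanParams | None = None
               ) -> tuple[KalmanState, BBox]:
    """One constant-velocity transition; returns the new state and its box.

    If the predicted area would become non-positive, the area velocity is
    clamped to zero before the transition (a shrinking box cannot collapse
    through zero area).
    """
    params = params or KalmanParams()
    x = state.x.copy()
    if x[2] + x[6] <= 0:
        x[6] = 0.0
    x = _F @ x
    P = _symmetrize(_F @ state.P @ _F.T + params.Q())
    new = KalmanState(x, P)
    return new, bbox_from_state(new)


def kf_update(state: KalmanState, measurement, params: KalmanParams | None = None
              ) -> KalmanState:
    """Standard Kalman measurement update with ``z = (u, v, s, r)``.

    ``measurement`` may be a :class:`BBox` or a length-4 vector.
    """
    params = params or KalmanParams()
    if isinstance(measurement, BBox):
        z = measurement_from_bbox(measurement)
    else:
        z = np.asarray(measurement, dtype=float).reshape(_DIM_Z)
    if not np.all(np.isfinite(z)):
        raise ValueError(f"non-finite measurement: {z}")
    P, R = state.P, params.R()
    y = z - _H @ state.x
    S = _H @ P @ _H.T + R
    K = P @ _H.T @ np.linalg.solve(S, np.eye(_DIM_Z))
    x = state.x + K @ y
    # Joseph form keeps P symmetric positive semidefinite
    A = np.eye(_DIM_X) - K @ _H
    P = _symmetrize(A @ P @ A.T + K @ R @ K.T)
    return KalmanState(x, P)
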