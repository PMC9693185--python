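"""Kalman smoothing of keypoint trajectories.

Markerless pose estimators are applied per frame, so their keypoint
trajectories carry frame-to-frame jitter that no real limb exhibits.  This
module removes that jitter by running a Kalman filter followed by a
Rauch–Tung–Striebel (RTS) backward pass over each keypoint's coordinate
time series, independently per axis (x, y, z): smoothing is a pure
time-series operation, so axes never mix.

Two state-space models are provided:

* ``constant_velocity`` (default) — state (position, velocity); suits human
  motion, where keypoints have strong velocity continuity, and does not lag
  fast movements the way a position-only model would;
* ``constant_position`` — scalar random-walk state, heavier smoothing.

Missing (invisible) samples receive the model prediction: the filter runs
its time update without a measurement update for those frames, and the RTS
pass interpolates through the gap.  Their visibility flags stay False.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .pose import PoseSequence


@dataclass(frozen=True)
class KalmanConfig:
    """State-space model and noise levels for the smoother.

    Parameters
    ----------
    model
        ``constant_velocity`` or ``constant_position``.
    q
        Process-noise intensity (per unit time); how much the true signal
        may deviate from the motion model.  Default 1e-3 in h-normalized
        units (person height = 1).
    r
        Measurement-noise variance of the keypoint detector.  Default 1e-2
        in h-normalized units.
    p0
        Initial state variance (diagonal).
    dt
        Frame interval; 1 frame by default.
    mode
        ``smooth`` (filter + RTS backward pass, default) or ``filter``
        (causal forward pass only).
    """

    model: str = "constant_velocity"
    q: float = 1e-3
    r: float = 1e-2
    p0: float = 1.0
    dt: float = 1.0
    mode: str = "smooth"

    def __post_init__(self):
        if self.model not in ("constant_velocity", "constant_position"):
            raise ValidationError(f"unknown model {self.model!r}")
        if self.mode not in ("smooth", "filter"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.r <= 0 or self.q < 0 or self.p0 <= 0 or self.dt <= 0:
            raise ValidationError("require r > 0, q >= 0, p0 > 0, dt > 0")

    def matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(F, Q, H) for one time step."""
        dt = self.dt
        if self.model == "constant_position":
            F = np.array([[1.0]])
            Q = np.array([[self.q * dt]])
            H = np.array([[1.0]])
        else:
            F = np.array([[1.0, dt], [0.0, 1.0]])
            # discretized white-noise-acceleration process covariance
            Q = self.q * np.array(
                [[dt ** 3 / 3.0, dt ** 2 / 2.0], [dt ** 2 / 2.0, dt]]
            )
            H = np.array([[1.0, 0.0]])
        return F, Q, H


def kalman_smooth_1d(
    series: np.ndarray,
    cfg: KalmanConfig | None = None,
    observed: np.ndarray | None = None,
) -> np.ndarray:
    """Smooth one scalar time series; missing samples get the prediction.

    Parameters
    ----------
    series
        1-D array; entries where ``observed`` is False (or NaN when no mask
        is given) are treated as missing.
    cfg
        Smoother configuration; defaults to :class:`KalmanConfig()`.
    observed
        Optional boolean mask of valid samples.

    Returns the smoothed series, same length as the input.
    """
    cfg = cfg or KalmanConfig()
    z = np.asarray(series, dtype=float)
    if z.ndim != 1 or len(z) == 0:
        raise DegenerateInputError("series must be 1-D and non-empty")
    if observed is None:
        observed = np.isfinite(z)
    observed = np.asarray(observed, dtype=bool)
    if not observed.any():
        raise DegenerateInputError("all samples missing")

    F, Q, H = cfg.matrices()
    n_state = F.shape[0]
    T = len(z)
    eye = np.eye(n_state)
    r = np.array([[cfg.r]])

    first = int(np.argmax(observed))
    x = np.zeros(n_state)
    x[0] = z[first]  # first observed value, zero velocity
    P = cfg.p0 * eye

    x_pred = np.zeros((T, n_state))
    P_pred = np.zeros((T, n_state, n_state))
    x_filt = np.zeros((T, n_state))
    P_filt = np.zeros((T, n_state, n_state))

    for t in range(T):
        if t == 0:
            xp, Pp = x, P
        else:
            xp = F @ x_filt[t - 1]
            Pp = F @ P_filt[t - 1] @ F.T + Q
        x_pred[t], P_pred[t] = xp, Pp
        if observed[t]:
            S = H @ Pp @ H.T + r
            K = Pp @ H.T @ np.linalg.inv(S)
            innov = z[t] - (H @ xp)[0]
            x_filt[t] = xp + (K * innov).ravel()
            P_filt[t] = (eye - K @ H) @ Pp
        else:
            x_filt[t], P_filt[t] = xp, Pp

    if cfg.mode == "filter":
        return x_filt[:, 0]

    # RTS backward pass
    x_sm = x_filt.copy()
    P_sm = P_filt.copy()
    for t in range(T - 2, -1, -1):
        G = P_filt[t] @ F.T @ np.linalg.inv(P_pred[t + 1])
        x_sm[t] = x_filt[t] + G @ (x_sm[t + 1] - x_pred[t + 1])
        P_sm[t] = P_filt[t] + G @ (P_sm[t + 1] - P_pred[t + 1]) @ G.T
    return x_sm[:, 0]


def smooth_sequence(seq: PoseSequence, cfg: KalmanConfig | None = None) -> PoseSequence:
    """Smooth every (joint, axis) coordinate series of a sequence.

    Visibility is preserved: previously invisible samples are filled with
    the model prediction so downstream geometry stays finite, but their
    flags remain False and metrics continue to ignore them.
    """
    cfg = cfg or KalmanConfig()
    coords = seq.coords.copy()
    for j in range(seq.n_joints):
        obs = seq.visible[:, j]
        if not obs.any():
            continue  # never-seen joint: nothing to smooth
        for axis in range(seq.n_dims):
            try:
                coords[:, j, axis] = kalman_smooth_1d(
                    seq.coords[:, j, axis], cfg, observed=obs
                )
            except DegenerateInputError as e:
                name = seq.skeleton.joint_names[j]
                raise DegenerateInputError(
                    f"joint {name!r} axis {'xyz'[axis]}: {e}"
                ) from e
    return seq.with_coords(coords)
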