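"""Temporal denoising of landmark trajectories.

Each coordinate channel is passed through a causal 1-D constant-velocity
Kalman filter and then an exponential moving average (EMA).  Both stages
are strictly causal — no backward smoothing pass — mirroring a real-time
feedback loop where only past frames are available.

The EMA recurrence is ``y[t] = alpha * x[t] + (1 - alpha) * y[t-1]``
with ``y[0] = x[0]``: ``alpha`` weights the newest sample, so smaller
values smooth harder.  The default ``alpha = 0.3`` is the conventional
setting for 30 fps keypoint streams.

The Kalman state per channel is (position, velocity) with unit-step
transition; the default noise variances (measurement 1e-4, process 1e-5,
in normalized-image units squared) assume sub-pixel estimator jitter on
top of smooth limb motion and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pose_io import LandmarkStream


@dataclass(frozen=True)
class SmoothingParams:
    """Parameters of the Kalman-then-EMA smoothing cascade."""

    ema_alpha: float = 0.3
    kalman_process_var: float = 1e-5
    kalman_measurement_var: float = 1e-4

    def __post_init__(self) -> None:
        if not (0.0 < self.ema_alpha <= 1.0):
            raise ValueError(f"ema_alpha must be in (0, 1], got {self.ema_alpha}")
        if self.kalman_process_var <= 0 or self.kalman_measurement_var <= 0:
            raise ValueError("Kalman noise variances must be positive")


def ema_smooth(series, alpha: float) -> np.ndarray:
    """Exponential moving average, newest-sample weight ``alpha``."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot smooth an empty series")
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    y = np.empty_like(x)
    y[0] = x[0]
    for t in range(1, len(x)):
        y[t] = alpha * x[t] + (1.0 - alpha) * y[t - 1]
    return y


def kalman_smooth(series, params: SmoothingParams | None = None) -> np.ndarray:
    """Causal constant-velocity Kalman filter of a scalar series.

    State ``[position, velocity]`` with transition ``p' = p + v`` per
    frame, observation of position only.  Initialized at the first
    sample with zero velocity and a diffuse velocity prior.
    """
    params = params or SmoothingParams()
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot filter an empty series")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")

    q = params.kalman_process_var
    r = params.kalman_measurement_var
    # state mean and covariance
    m = np.array([x[0], 0.0])
    P = np.array([[r, 0.0], [0.0, 1.0]])
    F = np.array([[1.0, 1.0], [0.0, 1.0]])
    # process noise on the velocity component (discrete white-noise accel)
    Q = q * np.array([[0.25, 0.5], [0.5, 1.0]])
    H = np.array([1.0, 0.0])

    y = np.empty_like(x)
    y[0] = x[0]
    for t in range(1, len(x)):
        m = F @ m
        P = F @ P @ F.T + Q
        S = P[0, 0] + r
        K = P[:, 0] / S
        m = m + K * (x[t] - m[0])
        P = P - np.outer(K, P[0, :])
        y[t] = m[0]
    return y


def smooth_stream(stream: LandmarkStream, params: SmoothingParams | None = None) -> LandmarkStream:
    """Kalman-then-EMA smooth every landmark coordinate channel.

    Visibility, frame indexing and timestamps are untouched; the applied
    parameters are recorded in the output stream's metadata.
    """
    params = params or SmoothingParams()
    stream.require_nonempty()
    out = stream.copy()
    n, k, _ = stream.coords.shape
    for j in range(k):
        for c in range(3):
            chan = stream.coords[:, j, c]
            out.coords[:, j, c] = ema_smooth(kalman_smooth(chan, params), params.ema_alpha)
    out.metadata = dict(stream.metadata)
    out.metadata["smoothing"] = {
        "method": "kalman+ema",
        "ema_alpha": params.ema_alpha,
        "kalman_process_var": params.kalman_process_var,
        "kalman_measurement_var": params.kalman_measurement_var,
    }
    return out


def mean_frame_jitter(stream: LandmarkStream) -> float:
    """Mean frame-to-frame landmark displacement (jitter metric).

    Average over frames and landmarks of the Euclidean displacement of
    each landmark between consecutive frames; 0 for a motionless stream.
    """
    stream.require_nonempty()
    if stream.n_frames < 2:
        return 0.0
    d = np.diff(stream.coords, axis=0)
    return float(np.linalg.norm(d, axis=2).mean())
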