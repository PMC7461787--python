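"""One-dimensional linear Kalman filter shared by both pipeline passes.

State: the horizontal velocity v.  The process model integrates the
global-frame forward acceleration,

    predict:  v(n|n−1) = v(n−1) + Δt · a_GFx(n−1),
              p(n|n−1) = p(n−1) + μ Δt²,

and the (sparse) GNSS ground speed provides the measurement,

    gain:     K(n) = p(n|n−1) / (p(n|n−1) + η),
    update:   v(n|n) = v(n|n−1) + K(n) (z(n) − v(n|n−1)),
              p(n|n) = (1 − K(n)) p(n|n−1).

μ is the accelerometer (process) noise variance, (m/s²)², and enters the
covariance propagation scaled by the integration step; η is the GNSS
(measurement) noise variance, (m/s)².  A measurement of exactly 0 m/s means
"no measurement at this sample": prediction continues without an update.
That convention doubles as the zero-padding marker used when the 10 Hz GNSS
stream is placed on the 200 Hz IMU grid.  Consequence: a genuine standstill
reading never corrects the filter — a documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .errors import EmptySeriesError, ParameterError

__all__ = ["KalmanParams", "KalmanRun", "predict", "update", "run"]


@dataclass(frozen=True)
class KalmanParams:
    """Noise and initialisation parameters.

    mu : process (accelerometer) noise variance, (m/s²)².
    eta : measurement (GNSS) noise variance, (m/s)².
    dt : integration step, s (1/200 for the 200 Hz IMU grid).
    v0 : initial velocity, m/s (0 — the sprinter starts at rest).
    p0 : initial uncertainty, (m/s)²; defaults to eta (about one
         measurement's worth of doubt).
    """

    mu: float = 0.4
    eta: float = 0.01
    dt: float = 0.005
    v0: float = 0.0
    p0: float | None = None

    def __post_init__(self):
        if self.mu < 0:
            raise ParameterError("mu must be >= 0")
        if self.eta <= 0:
            raise ParameterError("eta must be > 0")
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if self.p0 is None:
            object.__setattr__(self, "p0", self.eta)
        if self.p0 < 0:
            raise ParameterError("p0 must be >= 0")


@dataclass
class KalmanRun:
    """Per-sample filter output.

    ``K`` holds the gain at samples where an update ran (NaN elsewhere);
    ``updated`` flags those samples.
    """

    t: np.ndarray
    v_est: np.ndarray
    p: np.ndarray
    K: np.ndarray
    updated: np.ndarray


def predict(v_prev: float, p_prev: float, a: float,
            params: KalmanParams) -> Tuple[float, float]:
    """One prediction step: integrate the acceleration, inflate p."""
    v_pred = v_prev + params.dt * a
    p_pred = p_prev + params.mu * params.dt ** 2
    return v_pred, p_pred


def update(v_pred: float, p_pred: float, z: float,
           params: KalmanParams) -> Tuple[float, float, float]:
    """One measurement update; returns (v_post, p_post, K)."""
    K = p_pred / (p_pred + params.eta)
    v_post = v_pred + K * (z - v_pred)
    p_post = (1.0 - K) * p_pred
    return v_post, p_post, K


def run(
    t: np.ndarray,
    a_gfx: np.ndarray,
    measurements: Tuple[Sequence[float], Sequence[float]] | Sequence[Tuple[float, float]],
    params: KalmanParams,
) -> KalmanRun:
    """Run the filter over an acceleration series with sparse measurements.

    Parameters
    ----------
    t, a_gfx : arrays
        200 Hz time stamps and forward acceleration.
    measurements : (times, values) pair of arrays, or list of (t, v) pairs
        Each measurement is attached to the nearest sample of ``t``.
        Zero-valued measurements are no-update markers.
    """
    t = np.asarray(t, dtype=float)
    a_gfx = np.asarray(a_gfx, dtype=float)
    n = len(t)
    if n == 0:
        raise EmptySeriesError("empty acceleration series")

    z = np.zeros(n)
    if measurements is not None:
        if isinstance(measurements, tuple) and len(measurements) == 2 and \
                np.ndim(measurements[0]) >= 1:
            tm = np.asarray(measurements[0], dtype=float)
            vm = np.asarray(measurements[1], dtype=float)
        else:
            pairs = np.asarray(list(measurements), dtype=float).reshape(-1, 2)
            tm, vm = pairs[:, 0], pairs[:, 1]
        if tm.size:
            idx = np.clip(np.searchsorted(t, tm), 0, n - 1)
            left = np.clip(idx - 1, 0, n - 1)
            use_left = np.abs(tm - t[left]) < np.abs(t[idx] - tm)
            idx = np.where(use_left, left, idx)
            z[idx] = vm

    v = np.empty(n)
    p = np.empty(n)
    K = np.full(n, np.nan)
    updated = np.zeros(n, dtype=bool)

    v_cur, p_cur = params.v0, params.p0
    if z[0] != 0.0:
        v_cur, p_cur, K[0] = update(v_cur, p_cur, z[0], params)
        updated[0] = True
    v[0], p[0] = v_cur, p_cur

    for i in range(1, n):
        v_cur, p_cur = predict(v_cur, p_cur, a_gfx[i - 1], params)
        if z[i] != 0.0:
            v_cur, p_cur, K[i] = update(v_cur, p_cur, z[i], params)
            updated[i] = True
        v[i], p[i] = v_cur, p_cur

    return KalmanRun(t=t, v_est=v, p=p, K=K, updated=updated)
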