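"""Gradient-descent orientation estimation and frame conversion.

The trunk sensor's attitude is tracked with a quaternion filter in the
style of the gradient-descent (Madgwick) AHRS: the gyroscope is integrated
through the quaternion exponential, and a gradient-descent step — scaled by
the gain β — pulls the attitude toward the orientation whose predicted
gravity direction matches the measured specific force.

Conventions
-----------
* Quaternions are Hamilton, scalar-first, unit norm, and *passive*
  sensor→global: v_G = q ⊗ (0, v_S) ⊗ q*.
* The global frame is X = direction of progression, Y = vertical (up),
  Z = lateral.  X is defined anew for every sprint by the mounting
  convention (no magnetometer, so there is no true heading).

Because the accelerometer measures gravity *plus* motion acceleration, the
corrective step is only trustworthy when the sensor is quasi-static.  The
correction is therefore gated: it is applied only where the windowed
maximum of the gyroscope norm and the deviation of the accelerometer norm
from g are both small.  During the sprint itself the attitude evolves by
pure gyroscope integration from the statically-initialised orientation,
which is what keeps the gravity-removal step unbiased under the large
horizontal accelerations of a sprint start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d

from .errors import DataError, EmptySeriesError, NoStaticPeriodError
from .io_formats import GRAVITY, ImuRecording

__all__ = [
    "Quaternion",
    "QuaternionSeries",
    "GlobalAcceleration",
    "quat_multiply",
    "quat_conjugate",
    "quat_rotate",
    "initial_orientation",
    "select_static_window",
    "run_orientation_filter",
    "to_global_acceleration",
]


Quaternion = np.ndarray  # shape (4,), scalar-first, unit norm


@dataclass
class QuaternionSeries:
    """One unit quaternion per IMU sample."""

    t: np.ndarray
    q: np.ndarray  # (n, 4)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if len(self.t) != len(self.q):
            raise DataError("t and q must have equal length")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class GlobalAcceleration:
    """Gravity-free acceleration in the global frame.

    ``a_gf`` is (n, 3); ``a_gfx`` is its first (forward) component.
    """

    t: np.ndarray
    a_gf: np.ndarray
    fs: float

    @property
    def a_gfx(self) -> np.ndarray:
        return self.a_gf[:, 0]

    def __len__(self) -> int:
        return len(self.t)


def quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product p ⊗ q (scalar-first)."""
    pw, px, py, pz = p
    qw, qx, qy, qz = q
    return np.array([
        pw * qw - px * qx - py * qy - pz * qz,
        pw * qx + px * qw + py * qz - pz * qy,
        pw * qy - px * qz + py * qw + pz * qx,
        pw * qz + px * qy - py * qx + pz * qw,
    ])


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) v by quaternion(s) q: q ⊗ (0, v) ⊗ q*.

    Accepts a single quaternion with one or many vectors, or matched
    (n, 4) / (n, 3) arrays.  Vectorised via the cross-product identity
    v' = v + 2 w (u × v) + 2 u × (u × v), u = vector part of q.
    """
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    single = q.ndim == 1
    q2 = np.atleast_2d(q)
    v2 = np.atleast_2d(v)
    w = q2[:, :1]
    u = q2[:, 1:]
    uv = np.cross(u, v2)
    out = v2 + 2.0 * (w * uv + np.cross(u, uv))
    if single and v.ndim == 1:
        return out[0]
    return out


def _normalize(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q)


def initial_orientation(static_acc: np.ndarray) -> Quaternion:
    """Initial attitude from the mean specific force of the static window.

    Returns the minimal rotation taking ``static_acc`` to the global
    gravity reaction (0, g, 0).  Minimal means rotation about the axis
    perpendicular to both vectors, which introduces no spurious heading:
    with the sensor's forward axis mounted along the direction of
    progression, that axis projects onto global +X.

    Raises
    ------
    NoStaticPeriodError
        If ``‖static_acc‖`` deviates from g by more than 20% — the sensor
        was not at rest.
    """
    a = np.asarray(static_acc, dtype=float)
    norm = np.linalg.norm(a)
    if not (0.8 * GRAVITY <= norm <= 1.2 * GRAVITY):
        raise NoStaticPeriodError(
            f"static specific force {norm:.2f} m/s² is not within 20% of g"
        )
    ahat = a / norm
    yhat = np.array([0.0, 1.0, 0.0])
    axis = np.cross(ahat, yhat)
    s = np.linalg.norm(axis)
    c = float(np.dot(ahat, yhat))
    if s < 1e-12:
        if c > 0:
            return np.array([1.0, 0.0, 0.0, 0.0])
        # antipodal: gravity on -Y; flip about Z (any axis in the XZ plane works)
        return np.array([0.0, 0.0, 0.0, 1.0])
    angle = np.arctan2(s, c)
    axis = axis / s
    half = 0.5 * angle
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def select_static_window(
    imu: ImuRecording,
    t_s: float,
    window: float = 1.0,
    search_back: float = 0.8,
    step: float = 0.05,
):
    """Mean specific force and mean angular rate over the stillest
    ``window`` seconds ending at or shortly before the detected start.

    The GNSS-derived start can trail the true motion onset (the receiver
    responds late), so a window ending exactly at t_s may already contain
    movement.  Candidate windows ending at t_s, t_s − step, …,
    t_s − search_back are scored by the variance of the specific-force
    norm — the standard stillness statistic — and the quietest one is used.

    Returns ``(acc_mean, gyro_mean)``.  The mean angular rate of a truly
    static window is the gyroscope bias (zero-rate calibration), which
    should be subtracted before integrating.
    """
    best = None
    best_var = np.inf
    ends = np.arange(0.0, search_back + 0.5 * step, step)
    for back in ends:
        hi = t_s - back
        lo = hi - window
        mask = (imu.t >= lo) & (imu.t <= hi)
        if mask.sum() < 10:
            continue
        norms = np.linalg.norm(imu.acc[mask], axis=1)
        var = float(np.var(norms))
        if var < best_var - 1e-15:
            best_var = var
            best = (imu.acc[mask].mean(axis=0), imu.gyr[mask].mean(axis=0))
    if best is None:
        raise NoStaticPeriodError("no usable static window before the start")
    return best


def _gradient_step(q: np.ndarray, ahat: np.ndarray) -> np.ndarray:
    """Normalised gradient of the gravity-alignment objective.

    The objective is F(q) = ĝ_S(q) − â where ĝ_S = Rᵀ(q)·(0, 1, 0) is the
    gravity direction the attitude predicts in the sensor frame.  Returns
    ∇F / ‖∇F‖ (zero if the gradient vanishes).
    """
    w, x, y, z = q
    f1 = 2.0 * (x * y + w * z) - ahat[0]
    f2 = 1.0 - 2.0 * (x * x + z * z) - ahat[1]
    f3 = 2.0 * (y * z - w * x) - ahat[2]
    grad = np.array([
        2.0 * z * f1 - 2.0 * x * f3,
        2.0 * y * f1 - 4.0 * x * f2 - 2.0 * w * f3,
        2.0 * x * f1 + 2.0 * z * f3,
        2.0 * w * f1 - 4.0 * z * f2 + 2.0 * y * f3,
    ])
    n = np.linalg.norm(grad)
    if n < 1e-15:
        return np.zeros(4)
    return grad / n


def gravity_prediction_error(q: np.ndarray, acc: np.ndarray) -> float:
    """‖ĝ_S(q) − â‖ — the objective the corrective step descends."""
    a = np.asarray(acc, dtype=float)
    ahat = a / np.linalg.norm(a)
    w, x, y, z = q
    pred = np.array([2 * (x * y + w * z), 1 - 2 * (x * x + z * z),
                     2 * (y * z - w * x)])
    return float(np.linalg.norm(pred - ahat))


def run_orientation_filter(
    imu: ImuRecording,
    q0: Quaternion,
    beta: float = 0.1,
    gyro_gate: float = 0.25,
    acc_gate: float = 0.5,
    gate_window: float = 0.25,
    gyro_bias: np.ndarray | None = None,
) -> QuaternionSeries:
    """Track attitude over the recording.

    Per sample the gyroscope is integrated exactly (quaternion exponential
    of the midpoint angular rate), then — where the motion gates allow — a
    gradient-descent correction of magnitude ``beta``·dt pulls the attitude
    toward agreement with the measured gravity direction, and the
    quaternion is renormalised.

    Parameters
    ----------
    beta : float
        Correction gain, rad/s.  0 disables the accelerometer entirely
        (pure gyro integration).
    gyro_gate : float
        The correction is applied only where the windowed maximum of the
        gyroscope norm is below this (rad/s) …
    acc_gate : float
        … and the accelerometer norm is within this (m/s²) of g.
    gate_window : float
        Width (s) of the moving-maximum window on the gyroscope norm.
    gyro_bias : (3,) array, optional
        Zero-rate offset (e.g. the static-window mean from
        :func:`select_static_window`), subtracted before integration.
    """
    n = len(imu)
    if n == 0:
        raise EmptySeriesError("empty IMU recording")
    if beta < 0:
        raise ValueError("beta must be >= 0")

    t = imu.t
    acc = imu.acc
    gyr = imu.gyr
    if gyro_bias is not None:
        gyr = gyr - np.asarray(gyro_bias, dtype=float)

    gyro_norm = np.linalg.norm(gyr, axis=1)
    k = max(1, int(round(gate_window * imu.fs)))
    gyro_env = maximum_filter1d(gyro_norm, size=k, mode="nearest")
    acc_norm = np.linalg.norm(acc, axis=1)
    gate = (gyro_env <= gyro_gate) & (np.abs(acc_norm - GRAVITY) <= acc_gate) \
        & (acc_norm > 1e-9)

    out = np.empty((n, 4))
    q = _normalize(np.asarray(q0, dtype=float))
    out[0] = q
    for i in range(1, n):
        dt = t[i] - t[i - 1]
        wmid = 0.5 * (gyr[i - 1] + gyr[i])
        angle = np.linalg.norm(wmid) * dt
        if angle > 1e-12:
            axis = wmid / np.linalg.norm(wmid)
            half = 0.5 * angle
            dq = np.concatenate([[np.cos(half)], np.sin(half) * axis])
            q = quat_multiply(q, dq)
        if beta > 0.0 and gate[i]:
            q = q - beta * dt * _gradient_step(q, acc[i] / acc_norm[i])
        q = _normalize(q)
        out[i] = q
    return QuaternionSeries(t=t, q=out)


def to_global_acceleration(
    imu: ImuRecording, quats: QuaternionSeries
) -> GlobalAcceleration:
    """Rotate the specific force into the global frame and remove gravity.

    Implements a_GF = q ⊗ (0, a_SF) ⊗ q* − (0, g, 0); the forward component
    a_GFx is what feeds the Kalman filters.
    """
    if len(imu) != len(quats):
        raise DataError("IMU and quaternion series length mismatch")
    a_gf = quat_rotate(quats.q, imu.acc)
    a_gf = a_gf - np.array([0.0, GRAVITY, 0.0])
    return GlobalAcceleration(t=imu.t, a_gf=a_gf, fs=imu.fs)
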