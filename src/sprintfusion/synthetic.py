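"""Synthetic sprint sessions: ground-truth kinematics plus simulated sensors.

The generator emulates the measurement setup the estimation pipeline was
designed for: an athlete stands still for a few seconds, then sprints along a
straight line while wearing a trunk-mounted 200 Hz IMU and a 10 Hz GNSS
speed sensor, with a 50 Hz Doppler radar and photocell gates as references.

Ground truth
------------
The true speed follows one of two closed-form profiles,

* first order:  v(t) = v_max (1 − e^{−t/τ}),
* second order: v(t) = a e^{τ₁ t} − a e^{τ₂ t}  with τ₂ < τ₁ ≤ 0,

so that velocity, acceleration and distance are all analytic and every
downstream estimate can be checked against an exact value.  Trunk
orientation is a forward lean that relaxes linearly with distance covered,
plus a sinusoidal pitch oscillation at step frequency; both are
differentiable, so the simulated gyroscope is the exact angular rate.

Sensor imperfections (white noise, gyro bias, GNSS lag and smoothing, radar
noise) are controlled by :class:`NoiseModel` and are fully reproducible from
its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Dict, Tuple

import numpy as np
from scipy.optimize import brentq

from .errors import ParameterError
from .io_formats import (
    GRAVITY,
    GnssSeries,
    ImuRecording,
    RadarSeries,
    SessionConfig,
)

__all__ = [
    "GroundTruth",
    "NoiseModel",
    "make_velocity_profile",
    "simulate_imu",
    "simulate_gnss",
    "simulate_radar",
    "generate_session",
    "true_orientation",
]


@dataclass(frozen=True)
class GroundTruth:
    """Analytic sprint kinematics on the sprint clock (t = 0 at motion onset).

    ``v_true``/``a_true``/``x_true`` are vectorised callables returning 0 for
    t <= 0.  ``pitch`` is the forward trunk lean (rad, positive forward) and
    ``pitch_rate`` its exact time derivative.  ``T_true`` solves
    x_true(T) = distance.
    """

    v_true: Callable[[np.ndarray], np.ndarray]
    a_true: Callable[[np.ndarray], np.ndarray]
    x_true: Callable[[np.ndarray], np.ndarray]
    pitch: Callable[[np.ndarray], np.ndarray]
    pitch_rate: Callable[[np.ndarray], np.ndarray]
    distance: float
    T_true: float
    static_duration: float
    model: str
    params: Dict[str, float]


@dataclass(frozen=True)
class NoiseModel:
    """Sensor imperfection parameters.

    Defaults are consumer-grade orders of magnitude: white accelerometer and
    gyroscope noise, a constant gyroscope bias on every axis, GNSS
    under-responsiveness modelled as a pure lag plus a centred moving
    average, and white radar noise.  All simulators draw from independent
    streams derived from ``seed``, so a given (parameters, seed) pair yields
    bit-identical output.
    """

    acc_sigma: float = 0.3          # m/s² per axis
    gyro_sigma: float = 0.01        # rad/s per axis
    gyro_bias: float = 0.005        # rad/s, constant, every axis
    gnss_sigma: float = 0.15        # m/s
    gnss_lag: float = 0.3           # s
    gnss_smooth_window: float = 0.4  # s, centred moving average
    radar_sigma: float = 0.05       # m/s
    seed: int = 0

    def __post_init__(self):
        for name in ("acc_sigma", "gyro_sigma", "gnss_sigma", "radar_sigma"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.gnss_lag < 0:
            raise ParameterError("gnss_lag must be >= 0")

    @classmethod
    def noiseless(cls, seed: int = 0) -> "NoiseModel":
        """All imperfections switched off (exact sensors)."""
        return cls(
            acc_sigma=0.0, gyro_sigma=0.0, gyro_bias=0.0,
            gnss_sigma=0.0, gnss_lag=0.0, gnss_smooth_window=0.0,
            radar_sigma=0.0, seed=seed,
        )

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


def make_velocity_profile(
    model: str = "order2",
    params: Dict[str, float] | None = None,
    distance: float = 60.0,
    static_duration: float = 2.0,
    lean_start_deg: float = 45.0,
    lean_end_deg: float = 5.0,
    lean_distance: float = 20.0,
    osc_amp_deg: float = 5.0,
    osc_freq: float = 4.0,
) -> GroundTruth:
    """Build an analytic ground-truth sprint.

    Parameters
    ----------
    model : {"order1", "order2"}
        First-order profile ``v_max (1 − e^{−t/τ})`` (params ``v_max``,
        ``tau``) or second-order ``a e^{τ₁ t} − a e^{τ₂ t}`` (params ``a``,
        ``tau1``, ``tau2`` with ``tau2 < tau1 <= 0``).  Defaults give a
        realistic elite 60 m sprint (peak ≈ 10.1 m/s).
    distance : float
        Sprint distance D in metres; ``T_true`` solves x(T) = D.
    lean_* , osc_* :
        Trunk pitch trajectory: forward lean decreasing linearly from
        ``lean_start_deg`` to ``lean_end_deg`` over the first
        ``lean_distance`` metres, plus a step-frequency sinusoid of
        amplitude ``osc_amp_deg`` at ``osc_freq`` Hz while moving.
    """
    if distance <= 0:
        raise ParameterError("distance must be positive")
    if static_duration < 0:
        raise ParameterError("static_duration must be >= 0")

    if model == "order1":
        params = dict(params) if params else {"v_max": 9.5, "tau": 1.25}
        v_max, tau = params["v_max"], params["tau"]
        if v_max <= 0 or tau <= 0:
            raise ParameterError("order1 requires v_max > 0 and tau > 0")

        def v_true(t):
            t = np.asarray(t, dtype=float)
            return np.where(t > 0, v_max * -np.expm1(-np.maximum(t, 0) / tau), 0.0)

        def a_true(t):
            # right-continuous at the onset: a(0) is the initial push
            t = np.asarray(t, dtype=float)
            return np.where(t >= 0, (v_max / tau) * np.exp(-np.maximum(t, 0) / tau), 0.0)

        def x_true(t):
            t = np.asarray(t, dtype=float)
            tp = np.maximum(t, 0)
            return v_max * (tp + tau * np.expm1(-tp / tau))

    elif model == "order2":
        params = dict(params) if params else {"a": 10.5, "tau1": -0.005, "tau2": -0.8}
        a, tau1, tau2 = params["a"], params["tau1"], params["tau2"]
        if not (a > 0 and tau2 < tau1 <= 0):
            raise ParameterError("order2 requires a > 0 and tau2 < tau1 <= 0")

        def _exp_int(tau, t):
            # ∫₀ᵗ e^{τ s} ds, valid also in the τ → 0 limit
            if tau == 0:
                return t
            return np.expm1(tau * t) / tau

        def v_true(t):
            t = np.asarray(t, dtype=float)
            tp = np.maximum(t, 0)
            return np.where(t > 0, a * (np.exp(tau1 * tp) - np.exp(tau2 * tp)), 0.0)

        def a_true(t):
            # right-continuous at the onset: a(0⁺) = a (τ₁ − τ₂)
            t = np.asarray(t, dtype=float)
            tp = np.maximum(t, 0)
            val = a * (tau1 * np.exp(tau1 * tp) - tau2 * np.exp(tau2 * tp))
            return np.where(t >= 0, val, 0.0)

        def x_true(t):
            t = np.asarray(t, dtype=float)
            tp = np.maximum(t, 0)
            return a * (_exp_int(tau1, tp) - _exp_int(tau2, tp))

    else:
        raise ParameterError(f"unknown model {model!r}")

    # Solve x(T) = D; bracket by doubling, then root-find to 1e-9 s.
    t_hi = 1.0
    while x_true(t_hi) < distance:
        t_hi *= 2.0
        if t_hi > 1e6:
            raise ParameterError("profile never covers the requested distance")
    T_true = float(brentq(lambda t: float(x_true(t)) - distance, 1e-12, t_hi,
                          xtol=1e-9))

    lean0 = np.deg2rad(lean_start_deg)
    lean1 = np.deg2rad(lean_end_deg)
    amp = np.deg2rad(osc_amp_deg)
    slope = (lean1 - lean0) / lean_distance  # rad per metre
    w = 2.0 * np.pi * osc_freq
    ramp = 0.5  # s; the step oscillation builds up over the first strides,
    # keeping the angular rate continuous at the onset

    def pitch(t):
        t = np.asarray(t, dtype=float)
        tp = np.maximum(t, 0)
        x = x_true(t)
        lean = lean0 + slope * np.minimum(x, lean_distance)
        env = np.minimum(tp / ramp, 1.0)
        osc = np.where(t > 0, env * amp * np.sin(w * tp), 0.0)
        return lean + osc

    def pitch_rate(t):
        t = np.asarray(t, dtype=float)
        tp = np.maximum(t, 0)
        moving = (t > 0) & (x_true(t) < lean_distance)
        lean_dot = np.where(moving, slope * v_true(t), 0.0)
        env = np.minimum(tp / ramp, 1.0)
        env_dot = np.where(tp < ramp, 1.0 / ramp, 0.0)
        osc_dot = np.where(
            t > 0,
            amp * (env_dot * np.sin(w * tp) + env * w * np.cos(w * tp)),
            0.0)
        return lean_dot + osc_dot

    return GroundTruth(
        v_true=v_true, a_true=a_true, x_true=x_true,
        pitch=pitch, pitch_rate=pitch_rate,
        distance=float(distance), T_true=T_true,
        static_duration=float(static_duration),
        model=model, params=params,
    )


def _session_duration(gt: GroundTruth, tail: float) -> float:
    return gt.static_duration + gt.T_true + tail


def true_orientation(gt: GroundTruth, t_session: np.ndarray) -> np.ndarray:
    """Exact sensor-to-global quaternions (scalar-first, (n, 4)) at session
    times ``t_session``.

    The true rotation is a pure pitch: a rotation by −θ(t) about the global
    Z (lateral) axis, where θ is the forward lean.  Used as the oracle for
    the orientation filter.
    """
    tau = np.asarray(t_session, dtype=float) - gt.static_duration
    theta = gt.pitch(tau)
    half = -0.5 * theta
    q = np.zeros((len(theta), 4))
    q[:, 0] = np.cos(half)
    q[:, 3] = np.sin(half)
    return q


def _sensor_frame_specific_force(gt: GroundTruth, tau: np.ndarray) -> np.ndarray:
    """True specific force in the sensor frame at sprint times ``tau``."""
    a_x = gt.a_true(tau)
    theta = gt.pitch(tau)
    c, s = np.cos(theta), np.sin(theta)
    # f_GF = (a_x, g, 0); f_SF = R(-θ about Z)ᵀ f_GF
    f = np.zeros((len(tau), 3))
    f[:, 0] = c * a_x - s * GRAVITY
    f[:, 1] = s * a_x + c * GRAVITY
    return f


def simulate_imu(
    gt: GroundTruth,
    noise: NoiseModel,
    fs: float = 200.0,
    duration: float | None = None,
    tail: float = 2.0,
) -> ImuRecording:
    """Simulate the trunk IMU at ``fs`` Hz on the session clock.

    During the static window the true specific force is the gravity
    reaction seen through the initial lean; during the sprint the true
    global acceleration lies along X and is rotated into the sensor frame by
    the inverse of the true orientation.  White noise is added per axis and
    the gyroscope additionally carries a constant bias on every axis.
    """
    if duration is None:
        duration = _session_duration(gt, tail)
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    tau = t - gt.static_duration

    acc = _sensor_frame_specific_force(gt, tau)
    gyr = np.zeros((n, 3))
    gyr[:, 2] = -gt.pitch_rate(tau)

    rng = noise.rng(0)
    if noise.acc_sigma > 0:
        acc = acc + rng.normal(0.0, noise.acc_sigma, size=acc.shape)
    else:
        rng.normal(size=acc.shape)  # keep stream alignment across settings
    if noise.gyro_sigma > 0:
        gyr = gyr + rng.normal(0.0, noise.gyro_sigma, size=gyr.shape)
    else:
        rng.normal(size=gyr.shape)
    gyr = gyr + noise.gyro_bias

    return ImuRecording(t=t, acc=acc, gyr=gyr, fs=fs)


def simulate_gnss(
    gt: GroundTruth,
    noise: NoiseModel,
    fs: float = 10.0,
    duration: float | None = None,
    tail: float = 2.0,
) -> GnssSeries:
    """Simulate the 10 Hz GNSS ground speed.

    The device's sluggish response is emulated phenomenologically: the true
    speed is read ``gnss_lag`` seconds late and passed through a centred
    moving average of ``gnss_smooth_window`` seconds, after which white
    noise is added and the result clipped at zero.  Samples up to the end of
    the static period report exactly 0 (a standstill clamp, as consumer
    units do).
    """
    if duration is None:
        duration = _session_duration(gt, tail)
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    v = np.asarray(gt.v_true(t - gt.static_duration - noise.gnss_lag), dtype=float)

    k = int(round(noise.gnss_smooth_window * fs))
    if k > 1:
        k = k + 1 if k % 2 == 0 else k  # centred → odd length
        kernel = np.ones(k) / k
        v = np.convolve(np.pad(v, (k // 2, k // 2), mode="edge"), kernel,
                        mode="valid")

    rng = noise.rng(1)
    if noise.gnss_sigma > 0:
        v = v + rng.normal(0.0, noise.gnss_sigma, size=v.shape)
    else:
        rng.normal(size=v.shape)
    v = np.clip(v, 0.0, None)
    v[t <= gt.static_duration] = 0.0
    return GnssSeries(t=t, v=v, fs=fs)


def simulate_radar(
    gt: GroundTruth,
    noise: NoiseModel,
    fs: float = 50.0,
    duration: float | None = None,
    tail: float = 2.0,
) -> RadarSeries:
    """Simulate the reference radar: true speed on a 50 Hz grid starting at
    motion onset (the radar triggers on the start), plus white noise,
    clipped at zero."""
    if duration is None:
        duration = gt.T_true + tail
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    v = np.asarray(gt.v_true(t), dtype=float)
    rng = noise.rng(2)
    if noise.radar_sigma > 0:
        v = v + rng.normal(0.0, noise.radar_sigma, size=v.shape)
    else:
        rng.normal(size=v.shape)
    return RadarSeries(t=t, v=np.clip(v, 0.0, None), fs=fs)


def generate_session(
    gt: GroundTruth,
    noise: NoiseModel,
    mass: float = 75.0,
    tail: float = 2.0,
) -> Tuple[ImuRecording, GnssSeries, RadarSeries, SessionConfig]:
    """Simulate all three sensors on a common session clock and bundle them
    with a matching :class:`SessionConfig`.

    The photocell times are (static_duration, static_duration + T_true) by
    construction, i.e. the gates fire exactly at motion onset and at the
    distance crossing.
    """
    imu = simulate_imu(gt, noise, tail=tail)
    gnss = simulate_gnss(gt, noise, tail=tail)
    radar = simulate_radar(gt, noise, tail=tail)
    config = SessionConfig(
        distance=gt.distance,
        mass=mass,
        coarse_start=max(0.0, gt.static_duration - 1.5),
        photocell_times=(gt.static_duration, gt.static_duration + gt.T_true),
    )
    return imu, gnss, radar, config
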