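"""Phase 1: precise sprint detection and segmentation.

From a coarse, manually chosen window this stage (i) finds the precise
start t_s with a 0.3 m/s threshold on the GNSS speed, (ii) checks whether
the GNSS speed looks like a first-order exponential rise and escalates the
Kalman measurement noise η if it does not, (iii) runs the sprint-detection
Kalman filter, and (iv) integrates the velocity into a distance profile
whose crossing of the sprint distance D defines the end t_e.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares

from .errors import EmptySeriesError, NoSprintFoundError, SprintIncompleteError
from .io_formats import GnssSeries, SessionConfig
from .kalman import KalmanParams, KalmanRun, run as kalman_run
from .orientation import GlobalAcceleration

__all__ = [
    "SprintWindow",
    "EtaTuneResult",
    "detect_start",
    "zero_pad_upsample",
    "tune_eta",
    "integrate_velocity",
    "segment_sprint",
]

#: Bounds and start for the single-τ exponential fits (sprint time
#: constants are seconds-scale).
TAU_BOUNDS = (0.05, 30.0)
TAU_INIT = 1.0


@dataclass(frozen=True)
class SprintWindow:
    """Detected sprint interval on the session clock."""

    t_s: float
    t_e: float
    distance: float

    def __post_init__(self):
        if self.t_e <= self.t_s:
            raise ValueError("t_e must exceed t_s")

    @property
    def t_d(self) -> float:
        return self.t_e - self.t_s


@dataclass(frozen=True)
class EtaTuneResult:
    """Outcome of the exponential-behaviour check on the GNSS speed.

    ``eta_chosen`` is the nominal η when the fit is good (R² above the
    threshold) and the escalated value otherwise.
    """

    r2: float
    eta_chosen: float
    vmax_obs: float
    tau_hat: float


def detect_start(gnss: GnssSeries, coarse_start: float,
                 threshold: float = 0.3) -> float:
    """Precise start time from the GNSS speed.

    t_s is the time of the last sample at/below ``threshold`` before the
    first sample after ``coarse_start`` that exceeds it, so that the static
    window precedes any detected motion.
    """
    t, v = gnss.t, gnss.v
    candidates = np.flatnonzero((t >= coarse_start) & (v > threshold))
    if candidates.size == 0:
        raise NoSprintFoundError(
            f"GNSS speed never exceeds {threshold} m/s after t={coarse_start}"
        )
    first_above = candidates[0]
    below = np.flatnonzero(v[:first_above] <= threshold)
    if below.size == 0:
        # moving from the first sample on; fall back to the crossing itself
        return float(t[first_above])
    return float(t[below[-1]])


def zero_pad_upsample(gnss: GnssSeries, target_fs: float = 200.0,
                      t0: Optional[float] = None,
                      t1: Optional[float] = None):
    """Place each GNSS sample at its nearest instant of a ``target_fs`` grid;
    every other grid sample carries 0, the no-update marker.

    Returns ``(t_grid, values)``.  The grid spans [t0, t1] (defaults: the
    GNSS series' own span).
    """
    if len(gnss) == 0:
        raise EmptySeriesError("empty GNSS series")
    if target_fs < gnss.fs or (target_fs / gnss.fs) % 1 > 1e-9:
        raise ValueError("target_fs must be an integer multiple of the GNSS rate")
    if t0 is None:
        t0 = gnss.t[0]
    if t1 is None:
        t1 = gnss.t[-1]
    n = int(round((t1 - t0) * target_fs)) + 1
    t_grid = t0 + np.arange(n) / target_fs
    out = np.zeros(n)
    idx = np.clip(np.round((gnss.t - t0) * target_fs).astype(int), 0, n - 1)
    keep = (gnss.t >= t0 - 0.5 / target_fs) & (gnss.t <= t1 + 0.5 / target_fs)
    out[idx[keep]] = gnss.v[keep]
    return t_grid, out


def _r2(y: np.ndarray, resid: np.ndarray) -> float:
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -math.inf
    return 1.0 - ss_res / ss_tot


def tune_eta(gnss_segment: GnssSeries, config: SessionConfig) -> EtaTuneResult:
    """Escalate η when the GNSS speed does not rise exponentially.

    Subtracting the first-order model from its plateau gives
    v_max − v(t) = v_max e^{−t/τ}; that decay is least-squares fitted (single
    parameter τ) to v_max_obs − v over the segment.  A good fit
    (R² > ``config.r2_threshold``) keeps η at its nominal value; a bad fit
    escalates it by an order of magnitude — the filter then trusts the GNSS
    less.  Segments with fewer than five moving samples skip the fit and
    escalate conservatively.
    """
    v = gnss_segment.v
    if np.count_nonzero(v > 0) < 5:
        return EtaTuneResult(r2=math.nan, eta_chosen=config.eta_escalated,
                             vmax_obs=float(v.max(initial=0.0)),
                             tau_hat=math.nan)
    t = gnss_segment.t - gnss_segment.t[0]
    vmax_obs = float(v.max())
    y = vmax_obs - v

    def resid(theta):
        return vmax_obs * np.exp(-t / theta[0]) - y

    sol = least_squares(resid, x0=[TAU_INIT], bounds=([TAU_BOUNDS[0]], [TAU_BOUNDS[1]]))
    r2 = _r2(y, sol.fun)
    eta = config.eta if r2 > config.r2_threshold else config.eta_escalated
    return EtaTuneResult(r2=r2, eta_chosen=eta, vmax_obs=vmax_obs,
                         tau_hat=float(sol.x[0]))


def integrate_velocity(t: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Cumulative trapezoidal integral of the velocity; first value 0."""
    return cumulative_trapezoid(np.asarray(v, float), np.asarray(t, float),
                                initial=0.0)


def _distance_crossing(t: np.ndarray, x: np.ndarray, distance: float) -> float:
    """First time the (non-decreasing) distance profile reaches ``distance``,
    with linear interpolation between the bracketing samples."""
    above = np.flatnonzero(x >= distance)
    if above.size == 0:
        raise SprintIncompleteError(
            f"distance profile peaks at {x.max():.2f} m < {distance} m"
        )
    i = above[0]
    if i == 0:
        return float(t[0])
    frac = (distance - x[i - 1]) / (x[i] - x[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def segment_sprint(
    accel: GlobalAcceleration,
    gnss: GnssSeries,
    config: SessionConfig,
    t_s: Optional[float] = None,
    full_output: bool = False,
):
    """Run the sprint-detection pass and return the precise window.

    Pipeline: detect t_s → η tuning on the GNSS samples from t_s to the
    end of the coarse window → sprint-detection Kalman filter on the 200 Hz
    acceleration with the sparse GNSS updates → distance profile → t_e at
    the (interpolated) crossing of the sprint distance.

    With ``full_output=True`` also returns a dict with the η-tune result
    and the Kalman run.
    """
    if t_s is None:
        t_s = detect_start(gnss, config.coarse_start, config.start_threshold)

    seg_mask = gnss.t >= t_s
    gnss_seg = GnssSeries(t=gnss.t[seg_mask], v=gnss.v[seg_mask], fs=gnss.fs)
    tune = tune_eta(gnss_seg, config)

    # The filter starts inside the static period (where v = 0 is exact) and
    # free-runs through the true motion onset; GNSS zeros are no-update
    # markers, so updates begin only once the receiver reports motion.
    # This matters because the GNSS-derived t_s trails the true onset: a
    # filter started at t_s from rest would miss the velocity already built.
    t_run0 = t_s - config.static_window
    acc_mask = accel.t >= t_run0
    t = accel.t[acc_mask]
    a = accel.a_gfx[acc_mask]
    if t.size == 0 or not np.any(t >= t_s):
        raise EmptySeriesError("no acceleration samples after t_s")
    params = KalmanParams(mu=config.mu, eta=tune.eta_chosen, dt=1.0 / accel.fs)
    # the sample at t_s itself is at/below the start threshold — by the
    # detection rule it precedes motion and provides no update
    meas = gnss_seg.t > t_s + 1e-12
    kr = kalman_run(t, a, (gnss_seg.t[meas], gnss_seg.v[meas]), params)

    # distance is integrated from t_s only
    sprint = kr.t >= t_s
    x = np.zeros_like(kr.t)
    x[sprint] = integrate_velocity(kr.t[sprint], kr.v_est[sprint])
    t_e = _distance_crossing(kr.t[sprint], x[sprint], config.distance)
    window = SprintWindow(t_s=float(t_s), t_e=t_e, distance=config.distance)
    if full_output:
        return window, {"eta_tune": tune, "kalman": kr, "distance_profile": x}
    return window
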