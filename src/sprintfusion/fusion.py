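"""Phase 2: GNSS-IMU fusion over the precisely segmented sprint.

The fusion filter is the same one-dimensional Kalman filter as the
detection pass (identical process and measurement models), re-initialised
at rest at t_s and fed only the precisely segmented data.  η is re-tuned on
the segmented GNSS samples.  The fused velocity is integrated to a distance
profile; the interpolated crossing of the sprint distance, minus t_s, is
the estimated sprint duration T_est.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import EmptySeriesError
from .io_formats import GnssSeries, SessionConfig
from .kalman import KalmanParams, run as kalman_run
from .orientation import GlobalAcceleration
from .segmentation import (
    EtaTuneResult,
    SprintWindow,
    _distance_crossing,
    integrate_velocity,
    tune_eta,
)

__all__ = ["VelocityEstimate", "estimate_velocity", "max_velocity",
           "strapdown_velocity"]


@dataclass
class VelocityEstimate:
    """Fused velocity over the sprint.

    ``t`` is relative to the sprint start t_s and spans [0, t_d]; ``x`` is
    the integrated distance on the same grid.  ``T_est`` is the estimated
    sprint duration (time to cover the sprint distance), which may differ
    slightly from t_d because the fusion pass re-tunes η and re-runs the
    filter.
    """

    t: np.ndarray
    v_est: np.ndarray
    p: np.ndarray
    x: np.ndarray
    T_est: float
    window: SprintWindow
    eta_tune: EtaTuneResult

    def __len__(self) -> int:
        return len(self.t)


def estimate_velocity(
    accel: GlobalAcceleration,
    gnss: GnssSeries,
    window: SprintWindow,
    config: SessionConfig,
) -> VelocityEstimate:
    """Run the GNSS-IMU fusion filter over the segmented sprint.

    η is re-tuned on the GNSS samples inside [t_s, t_e]; the filter runs
    over [t_s, t_e + margin] (the margin lets the distance crossing be
    interpolated even if phase 1 slightly underestimated the duration), and
    the reported series is truncated to [t_s, t_e].
    """
    t_s, t_e = window.t_s, window.t_e
    seg_mask = (gnss.t >= t_s) & (gnss.t <= t_e)
    gnss_seg = GnssSeries(t=gnss.t[seg_mask], v=gnss.v[seg_mask], fs=gnss.fs)
    tune = tune_eta(gnss_seg, config)

    # Like the detection pass, the filter free-runs from inside the static
    # period (its rest initialisation is exact there) so no early velocity
    # is missed; only the precisely segmented GNSS samples update it.
    run_mask = (accel.t >= t_s - config.static_window) & \
        (accel.t <= t_e + config.margin)
    t = accel.t[run_mask]
    a = accel.a_gfx[run_mask]
    if t.size == 0 or not np.any(t >= t_s):
        raise EmptySeriesError("no acceleration samples inside the window")

    params = KalmanParams(mu=config.mu, eta=tune.eta_chosen, dt=1.0 / accel.fs)
    meas = gnss_seg.t > t_s + 1e-12  # the t_s sample precedes motion
    kr = kalman_run(t, a, (gnss_seg.t[meas], gnss_seg.v[meas]), params)
    sprint = kr.t >= t_s
    x = np.zeros_like(kr.t)
    x[sprint] = integrate_velocity(kr.t[sprint], kr.v_est[sprint])
    T_est = _distance_crossing(kr.t[sprint], x[sprint], window.distance) - t_s

    keep = sprint & (kr.t <= t_e + 1e-12)
    return VelocityEstimate(
        t=kr.t[keep] - t_s,
        v_est=kr.v_est[keep],
        p=kr.p[keep],
        x=x[keep],
        T_est=float(T_est),
        window=window,
        eta_tune=tune,
    )


def max_velocity(est: VelocityEstimate) -> float:
    """Maximum fused velocity over [t_s, t_e]."""
    if len(est) == 0:
        raise EmptySeriesError("empty velocity estimate")
    return float(np.max(est.v_est))


def strapdown_velocity(
    accel: GlobalAcceleration,
    window: SprintWindow,
    config: Optional[SessionConfig] = None,
) -> np.ndarray:
    """Pure strap-down velocity: the segmented sprint integrated from rest
    at t_s with the GNSS withheld entirely (no measurement updates).

    This is the IMU-only baseline: it starts from the detected start like
    the classical strapdown approach and accumulates whatever drift the
    orientation errors and gyroscope bias induce.  Returns (t_rel, v)
    arrays over [t_s, t_e], times relative to t_s.
    """
    mask = (accel.t >= window.t_s) & (accel.t <= window.t_e)
    t = accel.t[mask]
    if t.size == 0:
        raise EmptySeriesError("no acceleration samples inside the window")
    mu = config.mu if config is not None else 0.4
    params = KalmanParams(mu=mu, eta=0.01, dt=1.0 / accel.fs)
    kr = kalman_run(t, accel.a_gfx[mask], ([], []), params)
    return t - window.t_s, kr.v_est
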