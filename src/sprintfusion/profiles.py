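"""Exponential velocity models and force/power (F-V, P-V) profiling.

Two families describe a sprint's speed curve:

* first order,  v(t) = v_anchor (1 − e^{−t/τ}), with the amplitude anchored
  either at the observed maximum (``anchor="max"``) or at the end-of-sprint
  velocity (``anchor="end"``); only τ is fitted;
* second order, v(t) = a e^{τ₁ t} − a e^{τ₂ t} with a > 0 and
  τ₂ < τ₁ ≤ 0, which can rise and then decay and nests the first-order
  curve in the τ₁ → 0⁻ limit.

From the fitted curve and the athlete's mass M the mechanical profile
follows: a_mdl(t) analytically, F_mdl = M a_mdl, P_mdl = F_mdl · v_mdl, and
the theoretical parameters

* f0    = a_mdl(0), maximum force per unit mass (N/kg),
* v0    = velocity at zero acceleration (for order 2 at
          t* = ln(τ₁/τ₂)/(τ₂ − τ₁); for order 1 it is the anchor),
* pmax  = apex of P_mdl/M over time (W/kg).

Power is the product of force and velocity (dimensionally, W = N · m/s); a
``power_from="acceleration"`` flag computes F · a instead for comparison
with conventions that report that product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .errors import FitError
from .segmentation import TAU_BOUNDS, TAU_INIT

__all__ = [
    "FirstOrderFit",
    "SecondOrderFit",
    "MechanicalProfile",
    "fit_first_order",
    "fit_second_order",
    "mechanical_profile",
    "fv_pv_curves",
]

#: End velocity = mean of the samples in the last 0.1 s (robust to noise).
V_END_WINDOW = 0.1

_SECOND_ORDER_BOUNDS = ([1e-3, -0.5, -20.0], [100.0, 0.0, -1e-3])
#: Deterministic multipliers (a, τ1, τ2) for the restarts of the
#: second-order fit; the best sum of squares wins.
_RESTART_JITTER = [
    (1.1, 0.3, 0.5),
    (0.9, 3.0, 2.0),
    (1.2, 0.1, 1.5),
    (0.8, 1.5, 0.7),
]


@dataclass(frozen=True)
class FirstOrderFit:
    vmax_anchor: float
    tau: float
    anchor_kind: str  # "max" or "end"
    rms: float

    @property
    def order(self) -> int:
        return 1

    def velocity(self, t):
        t = np.asarray(t, dtype=float)
        return self.vmax_anchor * -np.expm1(-t / self.tau)

    def acceleration(self, t):
        t = np.asarray(t, dtype=float)
        return (self.vmax_anchor / self.tau) * np.exp(-t / self.tau)


@dataclass(frozen=True)
class SecondOrderFit:
    a: float
    tau1: float
    tau2: float
    rms: float

    @property
    def order(self) -> int:
        return 2

    def velocity(self, t):
        t = np.asarray(t, dtype=float)
        return self.a * (np.exp(self.tau1 * t) - np.exp(self.tau2 * t))

    def acceleration(self, t):
        t = np.asarray(t, dtype=float)
        return self.a * (self.tau1 * np.exp(self.tau1 * t)
                         - self.tau2 * np.exp(self.tau2 * t))

    @property
    def t_apex(self) -> float:
        """Time of zero acceleration (velocity apex); inf when τ₁ = 0."""
        if self.tau1 == 0.0:
            return math.inf
        return math.log(self.tau1 / self.tau2) / (self.tau2 - self.tau1)


Fit = Union[FirstOrderFit, SecondOrderFit]


@dataclass
class MechanicalProfile:
    """Modelled kinematics and kinetics on a time grid, plus the
    theoretical sprint parameters (per unit mass where noted)."""

    t: np.ndarray
    v_mdl: np.ndarray
    a_mdl: np.ndarray
    F_mdl: np.ndarray        # N
    P_mdl: np.ndarray        # W
    mass: float              # kg
    v0: float                # m/s
    f0: float                # N/kg
    pmax: float              # W/kg
    fit: Fit = None


def fit_first_order(t, v, anchor: str = "max") -> FirstOrderFit:
    """Fit v(t) = v_anchor (1 − e^{−t/τ}) with the amplitude fixed.

    ``anchor="max"`` uses max(v); ``anchor="end"`` uses the mean of the
    last 0.1 s.  τ is fitted by bounded least squares.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if anchor == "max":
        amp = float(np.max(v))
    elif anchor == "end":
        amp = float(np.mean(v[t >= t[-1] - V_END_WINDOW]))
    else:
        raise ValueError("anchor must be 'max' or 'end'")
    if amp <= 0:
        raise FitError(f"non-positive anchor velocity ({amp})")

    def resid(theta):
        return amp * -np.expm1(-t / theta[0]) - v

    sol = least_squares(resid, x0=[TAU_INIT],
                        bounds=([TAU_BOUNDS[0]], [TAU_BOUNDS[1]]))
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return FirstOrderFit(vmax_anchor=amp, tau=float(sol.x[0]),
                         anchor_kind=anchor, rms=rms)


def fit_second_order(t, v) -> SecondOrderFit:
    """Fit v(t) = a e^{τ₁ t} − a e^{τ₂ t} by bounded trust-region least
    squares (constraints a > 0, τ₂ < τ₁ ≤ 0) with multi-start.

    The base start is (max(v), −0.01, −1/τ̂) where τ̂ is the max-anchored
    first-order time constant, plus four deterministically jittered
    restarts; the lowest sum of squares wins, ties broken by smaller |τ₁|.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(t) < 10:
        raise FitError("need at least 10 samples for the second-order fit")

    tau_hat = fit_first_order(t, v, anchor="max").tau
    base = np.array([max(np.max(v), 1e-2), -0.01, -1.0 / tau_hat])
    lo, hi = (np.array(b) for b in _SECOND_ORDER_BOUNDS)

    def resid(theta):
        a, tau1, tau2 = theta
        return a * (np.exp(tau1 * t) - np.exp(tau2 * t)) - v

    best = None
    for mult in [(1.0, 1.0, 1.0)] + _RESTART_JITTER:
        x0 = np.clip(base * np.array(mult), lo, hi)
        try:
            sol = least_squares(resid, x0=x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        a, tau1, tau2 = sol.x
        if not (a > 0 and tau2 < tau1 <= 0):
            continue
        sse = float(np.sum(sol.fun ** 2))
        if best is None or sse < best[0] * (1 - 1e-12) or (
                abs(sse - best[0]) <= 1e-12 * max(best[0], 1.0)
                and abs(tau1) < abs(best[1][1])):
            best = (sse, sol.x, sol.fun)
    if best is None:
        raise FitError("second-order fit failed from every start")
    sse, (a, tau1, tau2), fun = best
    rms = float(np.sqrt(np.mean(fun ** 2)))
    return SecondOrderFit(a=float(a), tau1=float(tau1), tau2=float(tau2),
                          rms=rms)


def _pmax(fit: Fit, t_grid: np.ndarray) -> float:
    """Apex of v·a over the grid, refined by bounded golden-section."""
    power = fit.velocity(t_grid) * fit.acceleration(t_grid)
    i = int(np.argmax(power))
    lo = t_grid[max(i - 1, 0)]
    hi = t_grid[min(i + 1, len(t_grid) - 1)]
    if hi <= lo:
        return float(power[i])
    res = minimize_scalar(lambda s: -fit.velocity(s) * fit.acceleration(s),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(max(power[i], -res.fun))


def mechanical_profile(
    fit: Fit,
    mass: float,
    t_grid=None,
    power_from: str = "velocity",
) -> MechanicalProfile:
    """Evaluate the mechanical profile of a fitted velocity model.

    ``t_grid`` defaults to 2000 points over [0, t_end] where t_end is
    1.2 · t* for a second-order fit (5τ for first order).  ``power_from``
    selects P = F·v (default, dimensionally power) or P = F·a.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    if power_from not in ("velocity", "acceleration"):
        raise ValueError("power_from must be 'velocity' or 'acceleration'")

    if t_grid is None:
        if fit.order == 2 and math.isfinite(fit.t_apex):
            t_end = 1.2 * fit.t_apex
        else:
            t_end = 5.0 * getattr(fit, "tau", 1.0)
        t_grid = np.linspace(0.0, max(t_end, 1.0), 2000)
    t_grid = np.asarray(t_grid, dtype=float)

    v_mdl = fit.velocity(t_grid)
    a_mdl = fit.acceleration(t_grid)
    F = mass * a_mdl
    P = F * (v_mdl if power_from == "velocity" else a_mdl)

    if fit.order == 1:
        v0 = fit.vmax_anchor
        f0 = fit.vmax_anchor / fit.tau
        # closed form: P/M = v a peaks at e^{-t/τ} = 1/2 → v_anchor²/(4τ)
        pmax = fit.vmax_anchor ** 2 / (4.0 * fit.tau) \
            if power_from == "velocity" else _pmax_accel(fit, t_grid)
    else:
        f0 = fit.a * (fit.tau1 - fit.tau2)
        if math.isfinite(fit.t_apex):
            v0 = float(fit.velocity(fit.t_apex))
        else:
            v0 = fit.a  # τ₁ = 0 edge: the model's supremum
        pmax = _pmax(fit, t_grid) if power_from == "velocity" \
            else _pmax_accel(fit, t_grid)

    return MechanicalProfile(t=t_grid, v_mdl=v_mdl, a_mdl=a_mdl, F_mdl=F,
                             P_mdl=P, mass=mass, v0=float(v0), f0=float(f0),
                             pmax=float(pmax), fit=fit)


def _pmax_accel(fit: Fit, t_grid: np.ndarray) -> float:
    """Apex of a² over the grid (the alternative power convention)."""
    power = fit.acceleration(t_grid) ** 2
    return float(np.max(power))


def fv_pv_curves(profile: MechanicalProfile) -> Tuple[np.ndarray, np.ndarray]:
    """F-V and P-V curves (per unit mass) by parametric elimination of t.

    Restricted to the monotone-velocity portion (t ≤ t* for order 2) so
    force and power are single-valued functions of velocity.  Returns two
    (n, 2) arrays: columns (v, F/M) and (v, P/M).
    """
    fit = profile.fit
    if fit is not None and fit.order == 2 and math.isfinite(fit.t_apex):
        mask = profile.t <= fit.t_apex
    else:
        mask = np.ones(len(profile.t), dtype=bool)
    v = profile.v_mdl[mask]
    fv = np.column_stack([v, profile.F_mdl[mask] / profile.mass])
    pv = np.column_stack([v, profile.P_mdl[mask] / profile.mass])
    return fv, pv
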