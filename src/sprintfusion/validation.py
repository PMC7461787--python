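"""Agreement statistics for validating the estimated velocity and duration.

Error definitions (all against the radar/photocell references):

* velocity:  ε_v(t) = (v_ref(t) − v_test(t)) / max(v_ref) × 100%, RMS over
  the sprint;
* fit:       ε_fit(t) = v_ref(t) − v_fit(t), RMS in m/s;
* duration:  ε_t = (T_ref − T_test)/T_ref × 100% (negative ⇒ the duration
  was overestimated).

Cohort summaries are median and interquartile range of the per-trial RMS
values.  Agreement between paired scalar metrics (e.g. maximum velocity) is
assessed with Bland–Altman bias and limits of agreement and with Lin's
concordance correlation coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .io_formats import GnssSeries

__all__ = [
    "ErrorSummary",
    "AgreementStats",
    "resample_for_comparison",
    "velocity_error",
    "fit_error",
    "duration_error",
    "summarize",
    "bland_altman",
    "lin_ccc",
]


@dataclass(frozen=True)
class ErrorSummary:
    """Per-trial values with their median and (q25, q75)."""

    per_trial: Tuple[float, ...]
    median: float
    iqr: Tuple[float, float]


@dataclass(frozen=True)
class AgreementStats:
    """Bland–Altman bias and limits of agreement, optionally with Lin's
    concordance coefficient and its 95% CI."""

    bias: float
    loa: Tuple[float, float]
    ccc: Optional[float] = None
    ccc_ci: Optional[Tuple[float, float]] = None


def resample_for_comparison(
    t_est: np.ndarray,
    v_est: np.ndarray,
    gnss: GnssSeries,
    target_fs: float = 50.0,
):
    """Bring the 200 Hz estimate and the 10 Hz GNSS speed to a common 50 Hz.

    The estimate is decimated by keeping the first sample and every fourth
    sample after it (200/50 = 4, so the decimated instants coincide with
    the reference radar's grid); the GNSS speed is linearly interpolated
    onto the decimated grid with no extrapolation past its last sample.
    Returns ``(t50, v_est50, v_gnss50)`` truncated to the overlap.
    """
    t_est = np.asarray(t_est, dtype=float)
    v_est = np.asarray(v_est, dtype=float)
    if len(t_est) == 0:
        raise ValueError("empty estimate series")
    step = max(1, int(round(200.0 / target_fs)))
    t50 = t_est[::step]
    v50 = v_est[::step]
    keep = (t50 >= gnss.t[0]) & (t50 <= gnss.t[-1])
    t50, v50 = t50[keep], v50[keep]
    v_gnss50 = np.interp(t50, gnss.t, gnss.v)
    return t50, v50, v_gnss50


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def velocity_error(v_ref, v_test) -> float:
    """RMS of the normalised velocity error, percent.

    Per-sample error is (v_ref − v_test)/max(v_ref) × 100; the two series
    must already be on a common grid aligned at their sprint starts and are
    truncated to the shorter length.
    """
    v_ref = np.asarray(v_ref, dtype=float)
    v_test = np.asarray(v_test, dtype=float)
    n = min(len(v_ref), len(v_test))
    if n == 0:
        raise ValueError("empty series")
    v_ref, v_test = v_ref[:n], v_test[:n]
    vmax = float(np.max(v_ref))
    if vmax <= 0:
        raise ValueError("max(v_ref) must be positive for normalisation")
    return _rms((v_ref - v_test) / vmax * 100.0)


def fit_error(v_ref, v_fit) -> float:
    """Unnormalised RMS error of a fitted curve, m/s."""
    v_ref = np.asarray(v_ref, dtype=float)
    v_fit = np.asarray(v_fit, dtype=float)
    if len(v_ref) != len(v_fit):
        raise ValueError("series length mismatch")
    if len(v_ref) == 0:
        raise ValueError("empty series")
    return _rms(v_ref - v_fit)


def duration_error(T_ref: float, T_test: float) -> float:
    """Signed duration error, percent; negative means overestimated."""
    if T_ref <= 0:
        raise ValueError("T_ref must be positive")
    return (T_ref - T_test) / T_ref * 100.0


def summarize(values: Sequence[float]) -> ErrorSummary:
    """Median and interquartile range (linear-interpolation percentiles)."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("empty value list")
    q25, med, q75 = np.percentile(values, [25, 50, 75])
    return ErrorSummary(per_trial=tuple(values.tolist()),
                        median=float(med), iqr=(float(q25), float(q75)))


def bland_altman(x, y) -> AgreementStats:
    """Mean-difference agreement: bias = mean(x − y), limits of agreement
    bias ± 1.96 · sd (sample sd, n − 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series length mismatch")
    if len(x) < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementStats(bias=bias, loa=(bias - 1.96 * sd, bias + 1.96 * sd))


def lin_ccc(x, y) -> Tuple[float, Tuple[float, float]]:
    """Lin's concordance correlation coefficient with its 95% CI.

    ccc = 2 cov(x, y) / (var(x) + var(y) + (mean x − mean y)²), with
    population (1/n) moments; the confidence interval comes from the
    Fisher z-transform with standard error 1/√(n − 3).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series length mismatch")
    n = len(x)
    if n < 3:
        raise ValueError("need at least three pairs")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population (1/n)
    if vx == 0 and vy == 0:
        raise ValueError("both series have zero variance; ccc undefined")
    cov = float(np.mean((x - mx) * (y - my)))
    ccc = 2.0 * cov / (vx + vy + (mx - my) ** 2)
    ccc = min(max(ccc, -1.0), 1.0)  # guard rounding past the bounds
    c = min(max(ccc, -1.0 + 1e-15), 1.0 - 1e-15)
    z = math.atanh(c)
    half = 1.96 / math.sqrt(n - 3) if n > 3 else math.inf
    # the interval always brackets the point estimate, including the
    # saturated |ccc| = 1 case where the z-transform is clipped
    ci = (min(math.tanh(z - half), ccc), max(math.tanh(z + half), ccc))
    return float(ccc), ci
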