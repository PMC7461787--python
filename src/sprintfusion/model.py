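"""Model/Results facade over the estimation pipeline.

:class:`SprintVelocityModel` bundles one session's sensor streams with its
configuration; :meth:`SprintVelocityModel.fit` runs the full cascade —
orientation filter, sprint-detection pass, GNSS-IMU fusion pass, velocity
model fits, mechanical profile — and returns a
:class:`SprintVelocityResults` carrying every estimate with a ``summary()``
table, validation against reference instruments, and plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from . import fusion as _fusion
from . import orientation as _orientation
from . import profiles as _profiles
from . import segmentation as _segmentation
from . import validation as _validation
from .io_formats import (
    GnssSeries,
    ImuRecording,
    RadarSeries,
    SessionConfig,
    load_config,
    read_imu_csv,
    read_speed_csv,
    write_result_csv,
    write_summary_json,
)

__all__ = ["SprintVelocityModel", "SprintVelocityResults"]


class SprintVelocityModel:
    """One sprint session: trunk IMU + GNSS speed + configuration.

    Parameters
    ----------
    imu : ImuRecording
        200 Hz specific force and angular rate, sensor frame.
    gnss : GnssSeries
        10 Hz GNSS ground speed on the same session clock.
    config : SessionConfig
        Sprint distance, athlete mass, filter parameters.
    radar : RadarSeries, optional
        50 Hz reference speed (its clock starts at motion onset); only used
        for validation.

    Examples
    --------
    >>> model = SprintVelocityModel.from_synthetic(distance=60, seed=3)
    >>> res = model.fit()
    >>> print(res.summary())            # doctest: +SKIP
    """

    def __init__(self, imu: ImuRecording, gnss: GnssSeries,
                 config: SessionConfig, radar: Optional[RadarSeries] = None):
        self.imu = imu
        self.gnss = gnss
        self.config = config
        self.radar = radar
        self.ground_truth = None  # filled by from_synthetic

    @classmethod
    def from_csv(cls, imu_path, gnss_path, config_path,
                 radar_path=None) -> "SprintVelocityModel":
        config = load_config(config_path)
        imu = read_imu_csv(imu_path, acc_in_g=config.acc_in_g)
        gnss = read_speed_csv(gnss_path, kind="gnss")
        radar = read_speed_csv(radar_path, kind="radar") if radar_path else None
        return cls(imu, gnss, config, radar)

    @classmethod
    def from_synthetic(cls, distance: float = 60.0, seed: int = 0,
                       profile: str = "order2", noise=None, mass: float = 75.0,
                       **profile_kwargs) -> "SprintVelocityModel":
        """Simulate a session (see :mod:`sprintfusion.synthetic`) and wrap it."""
        from . import synthetic

        gt = synthetic.make_velocity_profile(model=profile,
                                             distance=distance,
                                             **profile_kwargs)
        if noise is None:
            noise = synthetic.NoiseModel(seed=seed)
        imu, gnss, radar, config = synthetic.generate_session(gt, noise,
                                                              mass=mass)
        model = cls(imu, gnss, config, radar)
        model.ground_truth = gt
        return model

    def fit(self) -> "SprintVelocityResults":
        """Run the full estimation cascade."""
        cfg = self.config
        t_s = _segmentation.detect_start(self.gnss, cfg.coarse_start,
                                         cfg.start_threshold)
        static_acc, _ = _orientation.select_static_window(
            self.imu, t_s, window=cfg.static_window)
        q0 = _orientation.initial_orientation(static_acc)
        quats = _orientation.run_orientation_filter(self.imu, q0,
                                                    beta=cfg.beta)
        accel = _orientation.to_global_acceleration(self.imu, quats)
        window, seg = _segmentation.segment_sprint(accel, self.gnss, cfg,
                                                   t_s=t_s, full_output=True)
        est = _fusion.estimate_velocity(accel, self.gnss, window, cfg)

        fits = {
            "order1_max": _profiles.fit_first_order(est.t, est.v_est, "max"),
            "order1_end": _profiles.fit_first_order(est.t, est.v_est, "end"),
            "order2": _profiles.fit_second_order(est.t, est.v_est),
        }
        profile = _profiles.mechanical_profile(fits["order2"], cfg.mass)

        return SprintVelocityResults(
            model=self, accel=accel, window=window, estimate=est,
            eta_pass1=seg["eta_tune"], eta_pass2=est.eta_tune,
            fits=fits, profile=profile,
        )


@dataclass
class SprintVelocityResults:
    """Estimates, diagnostics and derived profiles of one fitted session."""

    model: SprintVelocityModel
    accel: "_orientation.GlobalAcceleration"
    window: "_segmentation.SprintWindow"
    estimate: "_fusion.VelocityEstimate"
    eta_pass1: "_segmentation.EtaTuneResult"
    eta_pass2: "_segmentation.EtaTuneResult"
    fits: Dict[str, object]
    profile: "_profiles.MechanicalProfile"

    @property
    def T_est(self) -> float:
        return self.estimate.T_est

    @property
    def vmax(self) -> float:
        return _fusion.max_velocity(self.estimate)

    def summary(self) -> str:
        """Human-readable report of the session's estimates."""
        w, est, prof = self.window, self.estimate, self.profile
        f2 = self.fits["order2"]
        lines = [
            "Sprint velocity estimation",
            "=" * 54,
            f"distance              {w.distance:8.1f} m",
            f"start t_s             {w.t_s:8.3f} s",
            f"end t_e               {w.t_e:8.3f} s",
            f"segmented duration    {w.t_d:8.3f} s",
            f"estimated duration    {est.T_est:8.3f} s  (T_est)",
            f"maximum velocity      {self.vmax:8.3f} m/s",
            "-" * 54,
            f"eta pass 1            {self.eta_pass1.eta_chosen:8.3g} "
            f"(R2 = {self.eta_pass1.r2:.3f})",
            f"eta pass 2            {self.eta_pass2.eta_chosen:8.3g} "
            f"(R2 = {self.eta_pass2.r2:.3f})",
            "-" * 54,
            "velocity model fits (RMS, m/s):",
            f"  order 1 (v_max)     {self.fits['order1_max'].rms:8.4f}  "
            f"tau = {self.fits['order1_max'].tau:.3f} s",
            f"  order 1 (v_end)     {self.fits['order1_end'].rms:8.4f}  "
            f"tau = {self.fits['order1_end'].tau:.3f} s",
            f"  order 2             {f2.rms:8.4f}  "
            f"a = {f2.a:.3f}, tau1 = {f2.tau1:.4f}, tau2 = {f2.tau2:.4f}",
            "-" * 54,
            f"v0 (zero-force vel.)  {prof.v0:8.3f} m/s",
            f"f0 (max force/mass)   {prof.f0:8.3f} N/kg",
            f"pmax (apex power)     {prof.pmax:8.3f} W/kg",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        f2 = self.fits["order2"]
        return {
            "distance": self.window.distance,
            "t_s": self.window.t_s,
            "t_e": self.window.t_e,
            "t_d": self.window.t_d,
            "T_est": self.T_est,
            "vmax": self.vmax,
            "eta_pass1": self.eta_pass1.eta_chosen,
            "r2_pass1": self.eta_pass1.r2,
            "eta_pass2": self.eta_pass2.eta_chosen,
            "r2_pass2": self.eta_pass2.r2,
            "order1_max": {"vmax_anchor": self.fits["order1_max"].vmax_anchor,
                           "tau": self.fits["order1_max"].tau,
                           "rms": self.fits["order1_max"].rms},
            "order1_end": {"vmax_anchor": self.fits["order1_end"].vmax_anchor,
                           "tau": self.fits["order1_end"].tau,
                           "rms": self.fits["order1_end"].rms},
            "order2": {"a": f2.a, "tau1": f2.tau1, "tau2": f2.tau2,
                       "rms": f2.rms},
            "v0": self.profile.v0,
            "f0": self.profile.f0,
            "pmax": self.profile.pmax,
        }

    def save(self, velocity_csv=None, summary_json=None) -> None:
        if velocity_csv is not None:
            write_result_csv(velocity_csv, self.estimate.t,
                             self.estimate.v_est, self.estimate.p)
        if summary_json is not None:
            write_summary_json(summary_json, self.to_dict())

    # ------------------------------------------------------------------
    # validation against reference instruments
    # ------------------------------------------------------------------

    def validate(self, radar: Optional[RadarSeries] = None,
                 T_ref: Optional[float] = None,
                 include_baselines: bool = False) -> dict:
        """Errors against the radar and photocell references.

        Both speed series are re-timed to start at their respective sprint
        starts — the radar at its trigger (motion onset), the estimate at
        the detected t_s — and compared on the 50 Hz grid: the 200 Hz
        estimate is decimated by 4 (its decimated instants coincide with
        the radar grid) and the pair is truncated to the shorter series.
        Fitted velocity models are evaluated on the same grid.  With
        ``include_baselines=True`` the raw-GNSS (linearly interpolated to
        50 Hz) and pure strap-down velocity errors are computed under the
        identical protocol.
        """
        radar = radar if radar is not None else self.model.radar
        out = {}
        if radar is not None:
            v50 = self.estimate.v_est[::4]  # 200 -> 50 Hz
            t50 = self.estimate.t[::4]
            n = min(len(v50), len(radar.v))
            tr, vr = radar.t[:n], radar.v[:n]
            out["velocity_rms_pct"] = _validation.velocity_error(vr, v50[:n])
            out["vmax_radar"] = float(np.max(radar.v))
            out["vmax_est"] = self.vmax
            for name, fit in self.fits.items():
                out[f"fit_rms_{name}"] = _validation.fit_error(
                    vr, fit.velocity(tr))
            if include_baselines:
                g = self.model.gnss
                v_gnss = np.interp(t50[:n] + self.window.t_s, g.t, g.v)
                out["gnss_rms_pct"] = _validation.velocity_error(vr, v_gnss)
                sd_t, sd_v = _fusion.strapdown_velocity(
                    self.accel, self.window, self.model.config)
                v_sd = sd_v[::4]
                m = min(n, len(v_sd))
                out["strapdown_rms_pct"] = _validation.velocity_error(
                    vr[:m], v_sd[:m])
        if T_ref is None:
            T_ref = self.model.config.photocell_duration
        if T_ref is not None:
            out["duration_error_pct"] = _validation.duration_error(
                T_ref, self.T_est)
            out["T_ref"] = float(T_ref)
            out["T_est"] = self.T_est
        return out

    # ------------------------------------------------------------------
    # plotting
    # ------------------------------------------------------------------

    def plot(self, ax=None):
        """Overlay the fused velocity with the GNSS (and radar) speeds."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        est = self.estimate
        ax.plot(est.t, est.v_est, label="fused $v_{est}$", lw=1.5)
        g = self.model.gnss
        mask = (g.t >= self.window.t_s) & (g.t <= self.window.t_e)
        ax.plot(g.t[mask] - self.window.t_s, g.v[mask], "o", ms=3,
                label="GNSS")
        if self.model.radar is not None:
            r = self.model.radar
            mask = r.t <= self.window.t_d
            ax.plot(r.t[mask], r.v[mask], alpha=0.6, label="radar")
        ax.set_xlabel("time from sprint start (s)")
        ax.set_ylabel("velocity (m/s)")
        ax.legend()
        return ax

    def plot_profiles(self, ax=None):
        """F-V and P-V curves of the second-order fit (per unit mass)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        fv, pv = _profiles.fv_pv_curves(self.profile)
        ax.plot(fv[:, 0], fv[:, 1], label="F/M (N/kg)")
        ax2 = ax.twinx()
        ax2.plot(pv[:, 0], pv[:, 1], color="C1", label="P/M (W/kg)")
        ax.set_xlabel("velocity (m/s)")
        ax.set_ylabel("force per mass (N/kg)")
        ax2.set_ylabel("power per mass (W/kg)")
        return ax
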