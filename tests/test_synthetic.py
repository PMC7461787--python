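import math

import numpy as np
import pytest

from sprintfusion.errors import ParameterError
from sprintfusion.io_formats import GRAVITY
from sprintfusion.orientation import quat_rotate
from sprintfusion.synthetic import (
    GroundTruth,
    NoiseModel,
    generate_session,
    make_velocity_profile,
    simulate_gnss,
    simulate_imu,
    simulate_radar,
    true_orientation,
)

NOISELESS = NoiseModel.noiseless()


class TestVelocityProfiles:
    def test_order1_closed_form(self):
        gt = make_velocity_profile("order1", {"v_max": 10.0, "tau": 1.2})
        # v(τ) = v_max (1 − e^{−1}) at t = τ
        assert gt.v_true(1.2) == pytest.approx(10.0 * (1 - math.exp(-1)),
                                               abs=1e-9)
        assert float(gt.v_true(0.0)) == 0.0

    def test_order2_starts_at_zero_and_peaks_at_apex(self):
        a, t1, t2 = 10.5, -0.005, -0.8
        gt = make_velocity_profile("order2", {"a": a, "tau1": t1, "tau2": t2})
        assert float(gt.v_true(0.0)) == 0.0
        t_apex = math.log(t1 / t2) / (t2 - t1)
        v_apex = a * (math.exp(t1 * t_apex) - math.exp(t2 * t_apex))
        assert t_apex == pytest.approx(6.384, abs=1e-3)
        assert float(gt.v_true(t_apex)) == pytest.approx(v_apex, abs=1e-12)
        assert v_apex == pytest.approx(10.107, abs=1e-3)

    @pytest.mark.parametrize("distance", [30.0, 40.0, 60.0])
    def test_sprint_time_matches_numeric_integration(self, distance):
        gt = make_velocity_profile("order2", distance=distance)
        # independent oracle: dense trapezoidal quadrature of v_true
        t = np.linspace(0, 2 * gt.T_true, 400001)
        x = np.concatenate([[0.0], np.cumsum(
            0.5 * (gt.v_true(t)[1:] + gt.v_true(t)[:-1]) * np.diff(t))])
        T_num = np.interp(distance, x, t)
        assert gt.T_true == pytest.approx(T_num, abs=1e-4)
        assert gt.x_true(gt.T_true) == pytest.approx(distance, abs=1e-6)

    def test_parameter_constraints(self):
        with pytest.raises(ParameterError):
            make_velocity_profile("order1", {"v_max": -1.0, "tau": 1.0})
        with pytest.raises(ParameterError):
            make_velocity_profile("order2",
                                  {"a": 10.0, "tau1": -0.9, "tau2": -0.8})
        with pytest.raises(ParameterError):
            make_velocity_profile("order3")


class TestImuSimulator:
    def test_static_gravity_only_without_lean(self):
        gt = make_velocity_profile(lean_start_deg=0.0, lean_end_deg=0.0,
                                   osc_amp_deg=0.0)
        imu = simulate_imu(gt, NOISELESS)
        static = imu.t < gt.static_duration
        assert np.allclose(imu.acc[static], [0.0, GRAVITY, 0.0], atol=1e-12)
        assert np.allclose(imu.gyr[static], 0.0, atol=1e-12)

    def test_full_lean_puts_gravity_on_horizontal_axis(self):
        gt = make_velocity_profile(lean_start_deg=90.0, lean_end_deg=90.0,
                                   osc_amp_deg=0.0)
        imu = simulate_imu(gt, NOISELESS)
        static = imu.t < gt.static_duration
        # oracle: R(-90° about Z)ᵀ (0, g, 0) = (−g, 0, 0)
        assert np.allclose(imu.acc[static], [-GRAVITY, 0.0, 0.0], atol=1e-9)

    def test_seeded_determinism(self, default_truth):
        a = simulate_imu(default_truth, NoiseModel(seed=7))
        b = simulate_imu(default_truth, NoiseModel(seed=7))
        assert np.array_equal(a.acc, b.acc) and np.array_equal(a.gyr, b.gyr)

    def test_integrating_true_frame_acceleration_recovers_velocity(
            self, default_truth):
        """Rotating the noiseless specific force by the true orientation and
        integrating recovers v_true to < 1e-3 m/s (discretisation only)."""
        gt = default_truth
        imu = simulate_imu(gt, NOISELESS, duration=gt.static_duration + 10.0)
        q = true_orientation(gt, imu.t)
        a_gf = quat_rotate(q, imu.acc) - np.array([0.0, GRAVITY, 0.0])
        # integrate over the sprint itself (v = 0 at the onset sample)
        moving = imu.t >= gt.static_duration
        ax = a_gf[moving, 0]
        v = np.concatenate([[0.0], np.cumsum(
            0.5 * (ax[1:] + ax[:-1]) / imu.fs)])
        err = v - gt.v_true(imu.t[moving] - gt.static_duration)
        assert np.max(np.abs(err)) < 1e-3


class TestGnssSimulator:
    def test_noiseless_matches_truth_on_grid(self, default_truth):
        gnss = simulate_gnss(default_truth, NOISELESS)
        expected = default_truth.v_true(gnss.t - default_truth.static_duration)
        assert np.allclose(gnss.v, expected, atol=1e-12)

    def test_lag_underestimates_rising_profile(self):
        gt = make_velocity_profile("order1", {"v_max": 9.0, "tau": 1.3})
        noise = NoiseModel(acc_sigma=0, gyro_sigma=0, gyro_bias=0,
                           gnss_sigma=0, gnss_lag=0.4, gnss_smooth_window=0,
                           radar_sigma=0)
        lagged = simulate_gnss(gt, noise)
        exact = simulate_gnss(gt, NOISELESS)
        assert np.all(lagged.v <= exact.v + 1e-12)

    def test_static_samples_are_zero(self, default_truth):
        gnss = simulate_gnss(default_truth, NoiseModel(seed=3))
        assert np.all(gnss.v[gnss.t <= default_truth.static_duration] == 0.0)

    def test_seeded_determinism(self, default_truth):
        a = simulate_gnss(default_truth, NoiseModel(seed=5))
        b = simulate_gnss(default_truth, NoiseModel(seed=5))
        assert np.array_equal(a.v, b.v)


class TestRadarSimulator:
    def test_noiseless_matches_truth(self, default_truth):
        radar = simulate_radar(default_truth, NOISELESS)
        assert np.allclose(radar.v, default_truth.v_true(radar.t), atol=1e-12)

    def test_noise_level_on_constant_profile(self):
        # constant 8 m/s ground truth; the sample SD of the noise matches
        # the configured sigma (Monte-Carlo, n = 10^4)
        const = GroundTruth(
            v_true=lambda t: np.full_like(np.asarray(t, float), 8.0),
            a_true=lambda t: np.zeros_like(np.asarray(t, float)),
            x_true=lambda t: 8.0 * np.asarray(t, float),
            pitch=lambda t: np.zeros_like(np.asarray(t, float)),
            pitch_rate=lambda t: np.zeros_like(np.asarray(t, float)),
            distance=100.0, T_true=12.5, static_duration=0.0,
            model="order1", params={},
        )
        noise = NoiseModel(radar_sigma=0.1, seed=11)
        radar = simulate_radar(const, noise, duration=200.0)
        sd = np.std(radar.v - 8.0, ddof=1)
        assert len(radar) > 10_000
        assert sd == pytest.approx(0.1, abs=0.01)


class TestGenerateSession:
    def test_photocell_duration_is_true_duration(self, default_truth):
        *_, config = generate_session(default_truth, NOISELESS)
        assert config.photocell_duration == pytest.approx(
            default_truth.T_true, abs=1e-12)

    def test_shorter_distance_shorter_sprint(self):
        t30 = make_velocity_profile(distance=30.0).T_true
        t60 = make_velocity_profile(distance=60.0).T_true
        assert t30 < t60

    def test_seeds_change_noise_not_truth(self, default_truth):
        imu1, gnss1, *_ = generate_session(default_truth, NoiseModel(seed=1))
        imu2, gnss2, *_ = generate_session(default_truth, NoiseModel(seed=2))
        assert not np.array_equal(imu1.acc, imu2.acc)
        assert not np.array_equal(gnss1.v, gnss2.v)
        assert np.array_equal(imu1.t, imu2.t)
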