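import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sprintfusion.errors import DataError, EmptySeriesError, NoStaticPeriodError
from sprintfusion.io_formats import GRAVITY, ImuRecording
from sprintfusion.orientation import (
    gravity_prediction_error,
    initial_orientation,
    quat_conjugate,
    quat_multiply,
    quat_rotate,
    run_orientation_filter,
    select_static_window,
    to_global_acceleration,
)
from sprintfusion.synthetic import NoiseModel, make_velocity_profile, simulate_imu


def _static_imu(n=400, fs=200.0, acc=(0.0, GRAVITY, 0.0), gyr=(0, 0, 0)):
    t = np.arange(n) / fs
    return ImuRecording(t=t, acc=np.tile(acc, (n, 1)),
                        gyr=np.tile(gyr, (n, 1)), fs=fs)


finite3 = st.lists(st.floats(-100, 100), min_size=3, max_size=3)
unit_angle = st.floats(-math.pi, math.pi)


class TestQuaternionAlgebra:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(finite3, unit_angle, finite3)
    def test_rotation_is_an_isometry_and_conjugate_inverts(self, axis, angle, v):
        axis = np.asarray(axis)
        if np.linalg.norm(axis) < 1e-6:
            axis = np.array([1.0, 0.0, 0.0])
        axis = axis / np.linalg.norm(axis)
        q = np.concatenate([[math.cos(angle / 2)],
                            math.sin(angle / 2) * axis])
        v = np.asarray(v, float)
        rotated = quat_rotate(q, v)
        assert np.linalg.norm(rotated) == pytest.approx(
            np.linalg.norm(v), abs=1e-9)
        back = quat_rotate(quat_conjugate(q), rotated)
        assert np.allclose(back, v, atol=1e-9)

    def test_hamilton_product_unit(self):
        qi = np.array([0.0, 1.0, 0.0, 0.0])
        qj = np.array([0.0, 0.0, 1.0, 0.0])
        assert np.allclose(quat_multiply(qi, qj), [0, 0, 0, 1])  # i·j = k


class TestInitialOrientation:
    def test_already_level_gives_identity(self):
        q = initial_orientation([0.0, GRAVITY, 0.0])
        assert np.allclose(q, [1, 0, 0, 0], atol=1e-12)

    def test_quarter_turn_restores_gravity(self):
        q = initial_orientation([GRAVITY, 0.0, 0.0])
        restored = quat_rotate(q, [GRAVITY, 0.0, 0.0])
        assert np.allclose(restored, [0.0, GRAVITY, 0.0], atol=1e-9)

    def test_non_static_magnitude_rejected(self):
        with pytest.raises(NoStaticPeriodError):
            initial_orientation([0.0, 4.0, 0.0])


class TestOrientationFilter:
    def test_static_identity_fixed_point(self):
        imu = _static_imu()
        qs = run_orientation_filter(imu, np.array([1.0, 0, 0, 0]), beta=0.1)
        assert np.allclose(qs.q, [1, 0, 0, 0], atol=1e-12)

    def test_constant_rate_integrates_to_omega_t(self):
        # ω = 0.7 rad/s about Z for 2 s, beta = 0 (gyro only)
        omega, T, fs = 0.7, 2.0, 200.0
        n = int(T * fs) + 1
        imu = _static_imu(n=n, acc=(0, GRAVITY, 0), gyr=(0, 0, omega))
        qs = run_orientation_filter(imu, np.array([1.0, 0, 0, 0]), beta=0.0)
        qf = qs.q[-1]
        angle = 2.0 * math.atan2(np.linalg.norm(qf[1:]), qf[0])
        assert angle == pytest.approx(omega * T, abs=1e-6)

    def test_correction_descends_gravity_objective(self):
        # attitude perturbed 10 deg from the gravity-consistent one; static
        # input; the prediction error must decrease monotonically
        half = math.radians(10.0) / 2
        q0 = np.array([math.cos(half), 0.0, 0.0, math.sin(half)])
        imu = _static_imu(n=200)
        qs = run_orientation_filter(imu, q0, beta=0.1)
        errs = [gravity_prediction_error(q, imu.acc[i])
                for i, q in enumerate(qs.q[:100])]
        diffs = np.diff(errs)
        assert np.all(diffs < 0)

    def test_unit_norm_throughout_on_noisy_sprint(self):
        gt = make_velocity_profile(distance=30.0)
        imu = simulate_imu(gt, NoiseModel(seed=2))
        qs = run_orientation_filter(imu, np.array([1.0, 0, 0, 0]), beta=0.1)
        norms = np.linalg.norm(qs.q, axis=1)
        assert np.max(np.abs(norms - 1.0)) < 1e-9

    def test_empty_input_rejected(self):
        imu = _static_imu(n=2)
        imu.t = imu.t[:0]
        imu.acc = imu.acc[:0]
        imu.gyr = imu.gyr[:0]
        with pytest.raises(EmptySeriesError):
            run_orientation_filter(imu, np.array([1.0, 0, 0, 0]))


class TestGlobalAcceleration:
    def test_gravity_removed_at_rest(self):
        imu = _static_imu()
        qs = run_orientation_filter(imu, np.array([1.0, 0, 0, 0]), beta=0.1)
        acc = to_global_acceleration(imu, qs)
        assert np.allclose(acc.a_gf, 0.0, atol=1e-12)
        assert np.allclose(acc.a_gfx, 0.0, atol=1e-12)

    def test_static_horizontal_leakage_below_centimetre_scale(self):
        """With 0.02 m/s² accelerometer noise on a leaning static sensor the
        mean horizontal residual stays below 0.01 m/s²."""
        gt = make_velocity_profile(distance=60.0)
        noise = NoiseModel(acc_sigma=0.02, gyro_sigma=0.0, gyro_bias=0.0,
                           gnss_sigma=0, gnss_lag=0, gnss_smooth_window=0,
                           radar_sigma=0, seed=4)
        imu = simulate_imu(gt, noise)
        static = imu.t <= gt.static_duration - 0.5
        acc_mean, _ = select_static_window(imu, gt.static_duration - 0.5)
        q0 = initial_orientation(acc_mean)
        qs = run_orientation_filter(imu, q0, beta=0.1)
        acc = to_global_acceleration(imu, qs)
        assert abs(np.mean(acc.a_gfx[static])) < 0.01

    def test_noiseless_sprint_recovers_true_acceleration(self):
        """Simulator as oracle: on an exact sprint the pipeline's global
        forward acceleration matches the analytic one to < 0.05 m/s² RMS."""
        gt = make_velocity_profile(distance=60.0)
        imu = simulate_imu(gt, NoiseModel.noiseless())
        acc_mean, _ = select_static_window(imu, gt.static_duration)
        q0 = initial_orientation(acc_mean)
        qs = run_orientation_filter(imu, q0, beta=0.1)
        acc = to_global_acceleration(imu, qs)
        a_true = gt.a_true(imu.t - gt.static_duration)
        rms = np.sqrt(np.mean((acc.a_gfx - a_true) ** 2))
        assert rms < 0.05

    def test_length_mismatch_rejected(self):
        imu = _static_imu(n=10)
        qs = run_orientation_filter(imu, np.array([1.0, 0, 0, 0]))
        qs.q = qs.q[:5]
        qs.t = qs.t[:5]
        with pytest.raises(DataError):
            to_global_acceleration(imu, qs)
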