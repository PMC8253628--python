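"""Quaternion attitude estimation: initialization, integration, extraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from footmotion.attitude import (
    attitude_to_quaternion,
    compute_attitude,
    initial_attitude,
    quaternion_step,
    quaternion_to_attitude,
    rotation_matrix,
)
from footmotion.preprocess import MotionSegment
from footmotion.recording import ValidationError

angles = st.floats(-1.3, 1.3, allow_nan=False)


def make_segment(accel, gyro, rate=100.0):
    return MotionSegment("r", 50, 0, accel, gyro, rate)


class TestInitialAttitude:
    def test_gravity_aligned_gives_zero_angles(self):
        state = initial_attitude(np.array([0.0, 0.0, 1.0]))
        assert (state.theta, state.phi, state.psi) == (0.0, 0.0, 0.0)

    def test_pitch_like_angle_from_x_component(self):
        state = initial_attitude(np.array([0.5, 0.0, math.sqrt(3) / 2]))
        assert state.theta == pytest.approx(math.pi / 6, abs=1e-9)

    def test_input_normalized_before_use(self):
        # raw components exceeding 1 g must not break the arcsin
        state = initial_attitude(np.array([3.0, 0.0, 4.0]))
        assert state.theta == pytest.approx(math.asin(0.6), abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValidationError):
            initial_attitude(np.zeros(3))


class TestAttitudeToQuaternion:
    def test_identity(self):
        np.testing.assert_allclose(attitude_to_quaternion(0, 0, 0), [1, 0, 0, 0])

    def test_half_turn_about_x(self):
        q = attitude_to_quaternion(0.0, 0.0, math.pi / 2)
        np.testing.assert_allclose(q, [math.sqrt(2) / 2, math.sqrt(2) / 2, 0, 0], atol=1e-12)

    @settings(derandomize=True, deadline=None)
    @given(angles, angles, angles)
    def test_unit_norm(self, theta, phi, psi):
        q = attitude_to_quaternion(theta, phi, psi)
        assert np.linalg.norm(q) == pytest.approx(1.0, abs=1e-12)


class TestQuaternionStep:
    @pytest.mark.parametrize("mode", ["standard", "paper_literal"])
    def test_zero_rate_fixed_point(self, mode):
        q = attitude_to_quaternion(0.3, -0.2, 0.5)
        q2 = quaternion_step(q, np.zeros(3), 0.01, mode)
        np.testing.assert_allclose(q2, q, atol=1e-12)

    @pytest.mark.parametrize("mode", ["standard", "paper_literal"])
    def test_norm_preserved(self, mode, rng):
        q = np.array([1.0, 0.0, 0.0, 0.0])
        for _ in range(500):
            q = quaternion_step(q, rng.normal(0, 5, 3), 0.01, mode)
            assert abs(np.linalg.norm(q) - 1.0) < 1e-12

    def test_single_axis_closed_form(self):
        """Constant z-rate integration matches yaw = omega * t."""
        omega_z = 1.0
        dt = 0.01
        steps = int(round((math.pi / 4) / (omega_z * dt)))
        q = np.array([1.0, 0.0, 0.0, 0.0])
        for _ in range(steps):
            q = quaternion_step(q, np.array([0.0, 0.0, omega_z]), dt)
        _, _, yaw = quaternion_to_attitude(q)
        assert yaw == pytest.approx(omega_z * steps * dt, abs=1e-3)

    def test_non_unit_input_rejected(self):
        with pytest.raises(ValidationError):
            quaternion_step(np.array([1.0, 1.0, 0.0, 0.0]), np.zeros(3), 0.01)

    def test_bad_dt_rejected(self):
        with pytest.raises(ValidationError):
            quaternion_step(np.array([1.0, 0, 0, 0]), np.zeros(3), 0.0)


class TestQuaternionToAttitude:
    @pytest.mark.parametrize("mode", ["standard", "paper_literal"])
    def test_identity_quaternion(self, mode):
        assert quaternion_to_attitude(np.array([1.0, 0, 0, 0]), mode) == (0.0, 0.0, 0.0)

    @settings(derandomize=True, deadline=None)
    @given(st.floats(-0.2, 0.2), st.floats(-0.2, 0.2), st.floats(-0.2, 0.2))
    def test_round_trip_small_angles(self, theta, phi, psi):
        roll, pitch, yaw = quaternion_to_attitude(attitude_to_quaternion(theta, phi, psi))
        assert pitch == pytest.approx(theta, abs=1e-6)
        assert yaw == pytest.approx(phi, abs=1e-6)
        assert roll == pytest.approx(psi, abs=1e-6)

    def test_round_trip_sweep_below_gimbal(self, rng):
        lim = math.pi / 2 - 0.1
        for _ in range(200):
            theta = rng.uniform(-lim, lim)
            phi, psi = rng.uniform(-math.pi / 2, math.pi / 2, 2)
            roll, pitch, yaw = quaternion_to_attitude(
                attitude_to_quaternion(theta, phi, psi)
            )
            assert abs(pitch - theta) < 1e-6
            assert abs(yaw - phi) < 1e-6
            assert abs(roll - psi) < 1e-6

    def test_literal_mode_saturates_at_half_pi(self):
        q = np.array([math.sqrt(2) / 2, 0.0, 0.0, math.sqrt(2) / 2])
        roll, pitch, yaw = quaternion_to_attitude(q, "paper_literal")
        assert roll == pytest.approx(math.pi / 2, abs=1e-9)


class TestRotationMatrix:
    def test_identity_quaternion(self):
        np.testing.assert_allclose(rotation_matrix([1.0, 0, 0, 0]), np.eye(3))

    def test_orthogonality_and_determinant(self, rng):
        for _ in range(100):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            D = rotation_matrix(q)
            np.testing.assert_allclose(D @ D.T, np.eye(3), atol=1e-9)
            assert np.linalg.det(D) == pytest.approx(1.0, abs=1e-9)

    def test_trigonometric_identities(self, rng):
        """Matrix elements of the quaternion-built rotation equal the
        direction-cosine entries written in terms of the Euler angles."""
        for _ in range(200):
            theta = rng.uniform(-1.4, 1.4)   # pitch (y-rotation)
            phi = rng.uniform(-math.pi, math.pi)   # yaw (z-rotation)
            psi = rng.uniform(-math.pi, math.pi)   # roll (x-rotation)
            p0, p1, p2, p3 = attitude_to_quaternion(theta, phi, psi)
            assert 2 * (p1 * p3 - p0 * p2) == pytest.approx(-math.sin(theta), abs=1e-9)
            assert 2 * (p0 * p1 + p2 * p3) == pytest.approx(
                math.sin(psi) * math.cos(theta), abs=1e-9)
            assert p0**2 - p1**2 - p2**2 + p3**2 == pytest.approx(
                math.cos(theta) * math.cos(psi), abs=1e-9)
            assert 2 * (p0 * p3 + p1 * p2) == pytest.approx(
                math.sin(phi) * math.cos(theta), abs=1e-9)
            assert p0**2 + p1**2 - p2**2 - p3**2 == pytest.approx(
                math.cos(phi) * math.cos(theta), abs=1e-9)


class TestComputeAttitude:
    def test_rest_segment_constant_zero_attitude(self):
        accel = np.tile([0.0, 0.0, 1.0], (80, 1))
        gyro = np.zeros((80, 3))
        series = compute_attitude(make_segment(accel, gyro))
        np.testing.assert_allclose(series.angles, 0.0, atol=1e-12)
        np.testing.assert_allclose(
            series.quaternions, np.tile([1, 0, 0, 0], (80, 1)), atol=1e-12
        )

    def test_constant_rate_ramp(self):
        """A constant y-rate of 90 deg/s for 0.5 s yields 45 degrees of pitch."""
        w = 51
        accel = np.tile([0.0, 0.0, 1.0], (w, 1))
        gyro = np.tile([0.0, 90.0, 0.0], (w, 1))
        series = compute_attitude(make_segment(accel, gyro))
        assert series.pitch[-1] == pytest.approx(math.radians(45.0), abs=1e-3)
        # ramp is linear in time
        mid = series.pitch[25]
        assert mid == pytest.approx(math.radians(22.5), abs=1e-3)

    @pytest.mark.parametrize("mode", ["standard", "paper_literal"])
    def test_lengths_match_segment(self, mode, rng):
        w = 64
        accel = rng.normal([0, 0, 1], 0.05, (w, 3))
        gyro = rng.normal(0, 50, (w, 3))
        series = compute_attitude(make_segment(accel, gyro), mode)
        assert len(series) == w
        assert series.quaternions.shape == (w, 4)
        assert np.all(np.abs(np.linalg.norm(series.quaternions, axis=1) - 1) < 1e-9)
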