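"""Quaternion attitude-angle trajectories for motion segments.

The orientation of the ankle-mounted sensor is tracked per sample by
integrating the gyroscope through the quaternion kinematic equation.  The
initial orientation is estimated from the first accelerometer sample
(gravity direction), converted to a unit quaternion, advanced one
first-order step per sample, and converted back to Euler angles
(roll, pitch, yaw) at every step.

Two conventions are supported throughout:

``standard``
    Conventional aerospace Z-Y-X (yaw-pitch-roll) kinematics: the usual
    skew-symmetric rate matrix and four-quadrant Euler extraction with a
    clamped arcsin for pitch.

``paper_literal``
    The update-matrix row signs and Euler-extraction ratios are kept exactly
    as printed in the source formulation (which deviates from the
    conventional signs in two rows and two numerators), for auditability.
    Extraction uses principal-value arctangents; a vanishing denominator is
    treated as +0, so the angle saturates at +/- pi/2 with the sign of the
    numerator.

Quaternions are scalar-first arrays ``(p0, p1, p2, p3)`` and are
renormalized after every operation that could disturb the unit norm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import MotionSegment
from .recording import ValidationError

__all__ = [
    "AttitudeState",
    "AttitudeSeries",
    "initial_attitude",
    "attitude_to_quaternion",
    "quaternion_step",
    "quaternion_to_attitude",
    "rotation_matrix",
    "compute_attitude",
]

MODES = ("standard", "paper_literal")

_UNIT_TOL = 1e-6   # accepted deviation of an input quaternion from unit norm
_ZERO_DEN = 1e-12  # |denominator| below this is treated as +0 in literal mode


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValidationError(f"unknown euler mode {mode!r}; expected one of {MODES}")


def _normalize(q: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(q)
    if n == 0:
        raise ValidationError("cannot normalize a zero quaternion")
    return q / n


@dataclass
class AttitudeState:
    """Initial-angle triple (theta, phi, psi) and/or an extracted Euler triple.

    theta is the pitch-like angle (rotation about y), psi the roll-like angle
    (about x) and phi the yaw-like angle (about z); all radians.
    """

    theta: float = 0.0
    phi: float = 0.0
    psi: float = 0.0
    roll: float = 0.0
    pitch: float = 0.0
    yaw: float = 0.0


@dataclass
class AttitudeSeries:
    """Per-sample quaternions and Euler angles for one motion segment.

    ``quaternions`` is ``(W, 4)`` scalar-first; ``angles`` is ``(W, 3)`` with
    columns (pitch, roll, yaw) in radians; ``gimbal_flags`` marks samples
    where the pitch arcsin argument was clamped (standard mode only).
    """

    quaternions: np.ndarray
    angles: np.ndarray
    sample_rate: float
    mode: str
    gimbal_flags: np.ndarray

    @property
    def pitch(self) -> np.ndarray:
        return self.angles[:, 0]

    @property
    def roll(self) -> np.ndarray:
        return self.angles[:, 1]

    @property
    def yaw(self) -> np.ndarray:
        return self.angles[:, 2]

    def __len__(self) -> int:
        return len(self.angles)


def initial_attitude(a0: np.ndarray) -> AttitudeState:
    """Initial orientation angles from one accelerometer sample.

    The sample is first normalized to unit magnitude (raw components can
    exceed 1 g during motion, which would leave arcsin undefined).  Then

    * ``theta = arcsin(ax)`` (argument clamped to [-1, 1]),
    * ``psi   = arctan(-ay / az)`` (principal value; +/- pi/2 when az = 0),
    * ``phi   = arctan(magy0 / magx0)`` where the two helpers are rational
      expressions in the components with denominators grouped as
      ``1 - 2*(.^2 + .^2)``; the 0/0 case is defined as 0.

    At rest with gravity along +z, ``a0 = (0, 0, 1)`` gives all three angles
    equal to zero.
    """
    a0 = np.asarray(a0, dtype=float)
    if a0.shape != (3,):
        raise ValidationError(f"initial acceleration must be a 3-vector, got shape {a0.shape}")
    norm = np.linalg.norm(a0)
    if norm == 0 or not np.all(np.isfinite(a0)):
        raise ValidationError("initial acceleration must be finite with non-zero norm")
    ax, ay, az = a0 / norm

    theta = math.asin(min(1.0, max(-1.0, ax)))

    if az == 0.0:
        psi = 0.0 if ay == 0.0 else math.copysign(math.pi / 2, -ay)
    else:
        psi = math.atan(-ay / az)

    def _ratio(num: float, den: float) -> float:
        if den != 0.0:
            return num / den
        return 0.0 if num == 0.0 else math.copysign(math.inf, num)

    magx0 = _ratio(ax * ay + ax * az, 1.0 - 2.0 * (ay * ay + az * az))
    magy0 = _ratio(ax * ay + ay * az, 1.0 - 2.0 * (ax * ax + az * az))
    if magx0 == 0.0 and magy0 == 0.0:
        phi = 0.0
    elif magx0 == 0.0:
        phi = math.copysign(math.pi / 2, magy0)
    else:
        phi = math.atan(magy0 / magx0)

    return AttitudeState(theta=theta, phi=phi, psi=psi)


def attitude_to_quaternion(theta: float, phi: float, psi: float) -> np.ndarray:
    """Unit quaternion from the initial-angle triple (half-angle products).

    With psi as the x-rotation (roll-like), theta the y-rotation
    (pitch-like) and phi the z-rotation (yaw-like), this is the Z-Y-X
    composition quaternion.  The result is renormalized.
    """
    st, ct = math.sin(theta / 2), math.cos(theta / 2)
    sf, cf = math.sin(phi / 2), math.cos(phi / 2)
    sp, cp = math.sin(psi / 2), math.cos(psi / 2)
    q = np.array(
        [
            sp * st * sf + cp * ct * cf,
            sp * ct * cf - cp * st * sf,
            cp * st * cf + sp * ct * sf,
            cp * ct * sf - sp * st * cf,
        ]
    )
    return _normalize(q)


def _rate_matrix(omega: np.ndarray, mode: str) -> np.ndarray:
    """4x4 quaternion rate matrix Omega such that dq/dt = (1/2) Omega q."""
    wx, wy, wz = omega
    if mode == "standard":
        return np.array(
            [
                [0.0, -wx, -wy, -wz],
                [wx, 0.0, wz, -wy],
                [wy, -wz, 0.0, wx],
                [wz, wy, -wx, 0.0],
            ]
        )
    # literal mode: rows 2 and 4 carry the printed (unconventional) signs
    return np.array(
        [
            [0.0, -wx, -wy, -wz],
            [wx, 0.0, -wz, -wy],
            [wy, -wz, 0.0, wx],
            [-wz, wy, -wx, 0.0],
        ]
    )


def quaternion_step(
    q: np.ndarray,
    omega: np.ndarray,
    dt: float,
    mode: str = "standard",
) -> np.ndarray:
    """One first-order update ``q <- q + (dt/2) Omega(omega) q``, renormalized.

    ``omega`` is the body angular rate in rad/s.  The input must already be
    unit-norm within 1e-6.
    """
    _check_mode(mode)
    q = np.asarray(q, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if not dt > 0:
        raise ValidationError("dt must be positive")
    if abs(np.linalg.norm(q) - 1.0) > _UNIT_TOL:
        raise ValidationError("input quaternion must be unit-norm within 1e-6")
    q_new = q + 0.5 * dt * (_rate_matrix(omega, mode) @ q)
    return _normalize(q_new)


def _principal_atan(num: float, den: float) -> float:
    """Principal-value arctan(num/den) with a vanishing denominator read as +0."""
    if abs(den) < _ZERO_DEN:
        return 0.0 if num == 0.0 else math.copysign(math.pi / 2, num)
    return math.atan(num / den)


def quaternion_to_attitude(
    q: np.ndarray, mode: str = "standard"
) -> tuple[float, float, float]:
    """Euler triple (roll, pitch, yaw) in radians from a unit quaternion.

    Standard mode is the conventional Z-Y-X extraction (four-quadrant
    arctangents; pitch arcsin clamped near gimbal lock).  Literal mode
    evaluates the three printed arctangent ratios with principal values.
    """
    _check_mode(mode)
    p0, p1, p2, p3 = np.asarray(q, dtype=float)
    if mode == "standard":
        roll = math.atan2(2.0 * (p0 * p1 + p2 * p3), 1.0 - 2.0 * (p1 * p1 + p2 * p2))
        s = 2.0 * (p0 * p2 - p1 * p3)
        pitch = math.asin(min(1.0, max(-1.0, s)))
        yaw = math.atan2(2.0 * (p0 * p3 + p1 * p2), 1.0 - 2.0 * (p2 * p2 + p3 * p3))
        return roll, pitch, yaw
    roll = _principal_atan(2.0 * (p0 * p3 + p1 * p2), 1.0 - 2.0 * (p0 * p0 + p1 * p1))
    pitch_den = math.sqrt(
        4.0 * (p0 * p3 + p1 * p2) ** 2 + (1.0 - 2.0 * (p0 * p0 + p1 * p1)) ** 2
    )
    pitch = _principal_atan(2.0 * (p1 * p3 - p0 * p2), pitch_den)
    yaw = _principal_atan(2.0 * (p0 * p1 + p2 * p3), 1.0 - 2.0 * (p2 * p2 + p3 * p3))
    return roll, pitch, yaw


def rotation_matrix(q: np.ndarray) -> np.ndarray:
    """Body-to-reference direction cosine matrix of a unit quaternion."""
    p0, p1, p2, p3 = np.asarray(q, dtype=float)
    return np.array(
        [
            [
                p0 * p0 + p1 * p1 - p2 * p2 - p3 * p3,
                2.0 * (p1 * p2 - p0 * p3),
                2.0 * (p0 * p2 + p1 * p3),
            ],
            [
                2.0 * (p0 * p3 + p1 * p2),
                p0 * p0 - p1 * p1 + p2 * p2 - p3 * p3,
                2.0 * (p2 * p3 - p0 * p1),
            ],
            [
                2.0 * (p1 * p3 - p0 * p2),
                2.0 * (p0 * p1 + p2 * p3),
                p0 * p0 - p1 * p1 - p2 * p2 + p3 * p3,
            ],
        ]
    )


def compute_attitude(segment: MotionSegment, mode: str = "standard") -> AttitudeSeries:
    """Attitude trajectory of one segment by per-sample gyro integration.

    The initial quaternion comes from the segment's first accelerometer
    sample; each subsequent sample advances the quaternion one first-order
    step at ``dt = 1/sample_rate`` with the gyroscope reading converted from
    deg/s to rad/s.  Euler angles are extracted at every sample.
    """
    _check_mode(mode)
    w = segment.window_length
    dt = 1.0 / segment.sample_rate
    state = initial_attitude(segment.accel[0])
    q = attitude_to_quaternion(state.theta, state.phi, state.psi)

    gyro_rad = np.deg2rad(segment.gyro)
    quaternions = np.empty((w, 4))
    angles = np.empty((w, 3))
    flags = np.zeros(w, dtype=bool)
    for i in range(w):
        if i > 0:
            q = quaternion_step(q, gyro_rad[i], dt, mode=mode)
        quaternions[i] = q
        roll, pitch, yaw = quaternion_to_attitude(q, mode=mode)
        angles[i] = (pitch, roll, yaw)
        if mode == "standard":
            p0, p1, p2, p3 = q
            flags[i] = abs(2.0 * (p0 * p2 - p1 * p3)) > 1.0 - 1e-9
    return AttitudeSeries(
        quaternions=quaternions,
        angles=angles,
        sample_rate=segment.sample_rate,
        mode=mode,
        gimbal_flags=flags,
    )
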