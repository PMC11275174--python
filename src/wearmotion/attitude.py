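"""Six-axis attitude solution: complementary quaternion fusion with PI correction.

The solver keeps a scalar-first unit quaternion describing the sensor's
orientation.  Each step it

1. normalises the measured acceleration to a unit vector,
2. predicts the body-frame gravity direction from the current quaternion,
3. forms the cross product of measured and predicted gravity — an error
   signal proportional to the gyro integration drift,
4. corrects the gyro rates with a proportional-integral (PI) term built
   from that error (gains ``Kp``, ``Ki``),
5. advances the quaternion one first-order integration step using the
   corrected rates and half the sampling period, and
6. re-normalises the quaternion.

Euler angles follow the aerospace convention: yaw about Z, pitch about Y,
roll about X (intrinsic Z-Y-X), with Z pointing up at rest so that the
predicted gravity of the identity orientation is (0, 0, 1).

The first-order update leaves the quaternion norm at ``1 + O((|g| dt)^2)``
per step; the explicit re-normalisation in step 6 is what keeps the unit-norm
premise of the gravity prediction and Euler extraction true over long runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, Tuple

from .datamodel import ImuSample, Stream
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "Quaternion",
    "EulerAngles",
    "FusionGains",
    "FusionState",
    "normalize_accel",
    "gravity_from_quaternion",
    "error_vector",
    "fuse_step",
    "euler_from_quaternion",
    "quaternion_from_euler",
    "solve_stream",
]

Triple = Tuple[float, float, float]


@dataclass(frozen=True)
class Quaternion:
    """Scalar-first unit quaternion (q0, q1, q2, q3)."""

    q0: float = 1.0
    q1: float = 0.0
    q2: float = 0.0
    q3: float = 0.0

    def norm(self) -> float:
        return math.sqrt(
            self.q0 * self.q0 + self.q1 * self.q1 + self.q2 * self.q2 + self.q3 * self.q3
        )

    def normalized(self) -> "Quaternion":
        n = self.norm()
        if n == 0.0:
            raise DegenerateInputError("cannot normalise the zero quaternion")
        return Quaternion(self.q0 / n, self.q1 / n, self.q2 / n, self.q3 / n)

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.q0, self.q1, self.q2, self.q3)


@dataclass(frozen=True)
class EulerAngles:
    """Yaw/pitch/roll in radians: rotations about Z, Y and X respectively."""

    yaw: float
    pitch: float
    roll: float


@dataclass(frozen=True)
class FusionGains:
    """PI correction gains and the integration half-period.

    ``kp`` pulls the attitude toward the accelerometer's gravity direction,
    ``ki`` absorbs slow gyro bias, and ``half_t`` is half the sampling period
    in seconds (0.1 s at the nominal 0.2 s interval).
    """

    kp: float = 2.0
    ki: float = 0.005
    half_t: float = 0.1

    def __post_init__(self) -> None:
        if self.kp < 0 or self.ki < 0:
            raise ValidationError("gains must be non-negative")
        if not (self.half_t > 0):
            raise ValidationError("half_t must be positive")


@dataclass(frozen=True)
class FusionState:
    """Filter state: orientation estimate plus accumulated integral error."""

    q: Quaternion = field(default_factory=Quaternion)
    e_int: Triple = (0.0, 0.0, 0.0)
    gains: FusionGains = field(default_factory=FusionGains)


def normalize_accel(a: Triple) -> Triple:
    """Scale an acceleration triple to unit Euclidean norm.

    The norm is computed once from the raw components before any component
    is scaled, so the three divisions share one denominator.

    Raises
    ------
    DegenerateInputError
        For a zero-norm input (free-fall instant); callers skip the gravity
        correction for that sample instead of aborting the stream.
    """
    ax, ay, az = a
    n = math.sqrt(ax * ax + ay * ay + az * az)
    if n == 0.0:
        raise DegenerateInputError("zero-norm acceleration cannot be normalised")
    return (ax / n, ay / n, az / n)


def gravity_from_quaternion(q: Quaternion) -> Triple:
    """Body-frame gravity direction predicted by the orientation estimate.

    For a unit quaternion this is the third row of the body-to-world rotation
    matrix, i.e. the world 'up' axis expressed in body coordinates::

        Vx = 2 (q1 q3 - q0 q2)
        Vy = 2 (q0 q1 + q2 q3)
        Vz = q0^2 - q1^2 - q2^2 + q3^2

    and has unit norm whenever ``q`` does.
    """
    q0, q1, q2, q3 = q.q0, q.q1, q.q2, q.q3
    return (
        2.0 * (q1 * q3 - q0 * q2),
        2.0 * (q0 * q1 + q2 * q3),
        q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3,
    )


def error_vector(a_hat: Triple, v: Triple) -> Triple:
    """Cross product of measured and predicted gravity directions.

    Zero iff the two directions are parallel; its magnitude is proportional
    to the accumulated gyro integration error, which makes it a usable
    feedback signal for the PI correction.
    """
    ax, ay, az = a_hat
    vx, vy, vz = v
    return (ay * vz - az * vy, az * vx - ax * vz, ax * vy - ay * vx)


def fuse_step(state: FusionState, sample: ImuSample) -> FusionState:
    """Advance the fusion filter by one sample.

    When the accelerometer reading has positive norm the gyro rates are
    PI-corrected against the gravity error; a zero-norm reading (free fall)
    falls back to a pure gyro integration step.  The quaternion is
    re-normalised after every step.
    """
    for v in (*sample.a, *sample.w):
        if not math.isfinite(v):
            raise ValidationError(f"non-finite sample value {v!r}")

    kp, ki, half_t = state.gains.kp, state.gains.ki, state.gains.half_t
    gx, gy, gz = sample.w
    exi, eyi, ezi = state.e_int

    try:
        a_hat = normalize_accel(sample.a)
    except DegenerateInputError:
        a_hat = None

    if a_hat is not None:
        v = gravity_from_quaternion(state.q)
        ex, ey, ez = error_vector(a_hat, v)
        exi += ex * ki
        eyi += ey * ki
        ezi += ez * ki
        gx += kp * ex + exi
        gy += kp * ey + eyi
        gz += kp * ez + ezi

    q0, q1, q2, q3 = state.q.as_tuple()
    q0n = q0 + (-q1 * gx - q2 * gy - q3 * gz) * half_t
    q1n = q1 + (q0 * gx + q2 * gz - q3 * gy) * half_t
    q2n = q2 + (q0 * gy - q1 * gz + q3 * gx) * half_t
    q3n = q3 + (q0 * gz + q1 * gy - q2 * gx) * half_t

    q_new = Quaternion(q0n, q1n, q2n, q3n).normalized()
    return replace(state, q=q_new, e_int=(exi, eyi, ezi))


def euler_from_quaternion(q: Quaternion) -> EulerAngles:
    """Extract intrinsic Z-Y-X Euler angles from a unit quaternion.

    Yaw and roll use the two-argument arctangent so the full (-pi, pi]
    range is recovered; the pitch arcsine argument is clamped to [-1, 1]
    against floating-point overshoot near the gimbal poles.
    """
    q0, q1, q2, q3 = q.q0, q.q1, q.q2, q.q3
    yaw = math.atan2(2.0 * (q0 * q3 + q1 * q2), q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3)
    s = 2.0 * (q0 * q2 - q1 * q3)
    pitch = math.asin(max(-1.0, min(1.0, s)))
    roll = math.atan2(2.0 * (q0 * q1 + q2 * q3), q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3)
    return EulerAngles(yaw=yaw, pitch=pitch, roll=roll)


def quaternion_from_euler(e: EulerAngles) -> Quaternion:
    """Unit quaternion of an intrinsic Z-Y-X (yaw, pitch, roll) rotation."""
    cy, sy = math.cos(e.yaw / 2), math.sin(e.yaw / 2)
    cp, sp = math.cos(e.pitch / 2), math.sin(e.pitch / 2)
    cr, sr = math.cos(e.roll / 2), math.sin(e.roll / 2)
    return Quaternion(
        q0=cr * cp * cy + sr * sp * sy,
        q1=sr * cp * cy - cr * sp * sy,
        q2=cr * sp * cy + sr * cp * sy,
        q3=cr * cp * sy - sr * sp * cy,
    )


def solve_stream(
    samples: Iterable[ImuSample] | Stream,
    gains: FusionGains | None = None,
    initial: Quaternion | None = None,
) -> tuple[list[Quaternion], list[EulerAngles]]:
    """Run the fusion filter over a single-site sample sequence.

    Returns the per-sample quaternion and Euler-angle estimates (after the
    update for that sample).  When given a :class:`Stream` and no explicit
    gains, ``half_t`` defaults to half the stream's sampling interval.
    """
    if isinstance(samples, Stream):
        if gains is None:
            gains = FusionGains(half_t=samples.dt / 2.0)
        seq: Sequence[ImuSample] = samples.samples
    else:
        seq = list(samples)
    if gains is None:
        gains = FusionGains()
    state = FusionState(q=initial or Quaternion(), gains=gains)
    quats: list[Quaternion] = []
    eulers: list[EulerAngles] = []
    for s in seq:
        state = fuse_step(state, s)
        quats.append(state.q)
        eulers.append(euler_from_quaternion(state.q))
    return quats, eulers
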