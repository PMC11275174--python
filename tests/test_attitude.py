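"""Attitude solver: closed-form cases, oracles, and convergence behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from wearmotion import (
    BodySite,
    DegenerateInputError,
    EulerAngles,
    FusionGains,
    FusionState,
    ImuSample,
    Quaternion,
    TrajectorySpec,
    ValidationError,
    euler_from_quaternion,
    fuse_step,
    generate_imu_trajectory,
    quaternion_from_euler,
    solve_stream,
)
from wearmotion.attitude import error_vector, gravity_from_quaternion, normalize_accel

HALF = math.sqrt(2.0) / 2.0


def _sample(a, w, t=0.0):
    return ImuSample(site=BodySite.WAIST, t=t, a=tuple(a), w=tuple(w))


def _scipy_rot(q: Quaternion) -> Rotation:
    return Rotation.from_quat([q.q1, q.q2, q.q3, q.q0])  # scalar-last in scipy


unit_quaternions = st.builds(
    lambda v: Quaternion(*(np.array(v) / np.linalg.norm(v))),
    st.lists(
        st.floats(-1, 1).filter(lambda x: abs(x) > 1e-3), min_size=4, max_size=4
    ).filter(lambda v: np.linalg.norm(v) > 0.1),
)


class TestNormalizeAccel:
    @pytest.mark.parametrize(
        "a,expected",
        [((3, 0, 4), (0.6, 0.0, 0.8)), ((0, 0, 1), (0, 0, 1)), ((0, -2, 0), (0, -1, 0))],
    )
    def test_known_triples(self, a, expected):
        assert normalize_accel(a) == pytest.approx(expected, abs=1e-12)

    def test_zero_norm_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            normalize_accel((0.0, 0.0, 0.0))

    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=3).filter(
        lambda v: np.linalg.norm(v) > 1e-6))
    def test_unit_norm_and_direction(self, a):
        u = np.array(normalize_accel(tuple(a)))
        assert np.linalg.norm(u) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(np.cross(u, np.array(a) / np.linalg.norm(a)), 0, atol=1e-9)


class TestGravityFromQuaternion:
    @pytest.mark.parametrize(
        "q,expected",
        [
            (Quaternion(1, 0, 0, 0), (0, 0, 1)),
            (Quaternion(0, 1, 0, 0), (0, 0, -1)),
            (Quaternion(HALF, 0, HALF, 0), (-1, 0, 0)),
        ],
    )
    def test_closed_form_cases(self, q, expected):
        assert gravity_from_quaternion(q) == pytest.approx(expected, abs=1e-12)

    @given(unit_quaternions)
    def test_unit_norm_and_matches_rotation_matrix(self, q):
        v = np.array(gravity_from_quaternion(q))
        assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-9)
        # independent oracle: world 'up' expressed in body axes
        assert np.allclose(v, _scipy_rot(q).inv().apply([0, 0, 1]), atol=1e-9)


class TestErrorVector:
    def test_parallel_gives_zero(self):
        assert error_vector((0, 0, 1), (0, 0, 1)) == pytest.approx((0, 0, 0))

    def test_orthogonal_axes(self):
        assert error_vector((0, 0, 1), (1, 0, 0)) == pytest.approx((0, 1, 0))

    @given(st.lists(st.floats(-1, 1), min_size=6, max_size=6).filter(
        lambda v: np.linalg.norm(v[:3]) > 1e-3 and np.linalg.norm(v[3:]) > 1e-3))
    def test_matches_cross_product_oracle(self, v):
        a = np.array(v[:3]) / np.linalg.norm(v[:3])
        b = np.array(v[3:]) / np.linalg.norm(v[3:])
        assert np.allclose(error_vector(tuple(a), tuple(b)), np.cross(a, b), atol=1e-12)


class TestFuseStep:
    def test_aligned_static_input_is_fixed_point(self):
        state = FusionState()
        new = fuse_step(state, _sample(a=(0, 0, 9.81), w=(0, 0, 0)))
        assert new.q.as_tuple() == pytest.approx(state.q.as_tuple(), abs=1e-12)
        assert new.e_int == pytest.approx((0, 0, 0))

    def test_pure_gyro_substitution(self):
        w, h = 0.3, 0.05
        state = FusionState(gains=FusionGains(kp=0.0, ki=0.0, half_t=h))
        new = fuse_step(state, _sample(a=(0, 0, 0), w=(0, 0, w)))
        expected = np.array([1.0, 0.0, 0.0, w * h])
        expected /= np.linalg.norm(expected)
        assert new.q.as_tuple() == pytest.approx(tuple(expected), abs=1e-12)

    def test_zero_norm_accel_skips_correction_only(self):
        gains = FusionGains(kp=2.0, ki=0.1, half_t=0.05)
        free_fall = fuse_step(FusionState(gains=gains), _sample(a=(0, 0, 0), w=(0.1, 0, 0)))
        gyro_only = fuse_step(
            FusionState(gains=FusionGains(kp=0, ki=0, half_t=0.05)),
            _sample(a=(0, 0, 0), w=(0.1, 0, 0)),
        )
        assert free_fall.q.as_tuple() == pytest.approx(gyro_only.q.as_tuple())
        assert free_fall.e_int == (0.0, 0.0, 0.0)

    def test_norm_preserved_over_many_random_steps(self, rng):
        state = FusionState(gains=FusionGains(half_t=0.01))
        for _ in range(2000):
            state = fuse_step(
                state,
                _sample(a=rng.normal(0, 5, 3), w=rng.normal(0, 2, 3)),
            )
            assert abs(state.q.norm() - 1.0) < 1e-6

    def test_gyro_only_limit_matches_rotation_composition_oracle(self):
        """With Kp=Ki=0 the update is first-order rate integration: its error
        versus exact rotation composition stays O(dt^2) per step."""
        dt = 0.01
        w = np.array([0.4, -0.3, 0.5])
        state = FusionState(gains=FusionGains(kp=0, ki=0, half_t=dt / 2))
        exact = Rotation.identity()
        step = Rotation.from_rotvec(w * dt)
        for _ in range(100):
            state = fuse_step(state, _sample(a=(0, 0, 0), w=w))
            exact = exact * step  # body-frame rates compose on the right
        est = _scipy_rot(state.q)
        angle = (est.inv() * exact).magnitude()
        per_step_budget = float(np.linalg.norm(w) * dt) ** 2
        assert angle < 100 * per_step_budget

    def test_static_gravity_angle_non_increasing(self):
        """Noiseless static stream, Kp>0, Ki=0: the angle between estimated
        and measured gravity shrinks monotonically after a short burn-in."""
        true_q = quaternion_from_euler(EulerAngles(0.0, 0.4, -0.6))
        a_body = gravity_from_quaternion(true_q)
        state = FusionState(gains=FusionGains(kp=2.0, ki=0.0, half_t=0.1))
        angles = []
        for _ in range(60):
            state = fuse_step(state, _sample(a=a_body, w=(0, 0, 0)))
            v = np.array(gravity_from_quaternion(state.q))
            cosang = float(np.clip(np.dot(v, a_body), -1, 1))
            angles.append(math.acos(cosang))
        assert all(b <= a + 1e-12 for a, b in zip(angles[10:], angles[11:]))
        assert angles[-1] < 1e-3


class TestEulerConversions:
    def test_identity(self):
        e = euler_from_quaternion(Quaternion())
        assert (e.yaw, e.pitch, e.roll) == pytest.approx((0, 0, 0))

    def test_pure_yaw_quarter_turn(self):
        e = euler_from_quaternion(Quaternion(HALF, 0, 0, HALF))
        assert (e.yaw, e.pitch, e.roll) == pytest.approx((math.pi / 2, 0, 0))

    @given(
        st.floats(-math.pi + 1e-6, math.pi - 1e-6),
        st.floats(-math.radians(80), math.radians(80)),
        st.floats(-math.pi + 1e-6, math.pi - 1e-6),
    )
    def test_round_trip_away_from_gimbal_lock(self, yaw, pitch, roll):
        q = quaternion_from_euler(EulerAngles(yaw, pitch, roll))
        assert q.norm() == pytest.approx(1.0, abs=1e-12)
        e = euler_from_quaternion(q)
        assert (e.yaw, e.pitch, e.roll) == pytest.approx((yaw, pitch, roll), abs=1e-9)

    @given(
        st.floats(-math.pi + 1e-6, math.pi - 1e-6),
        st.floats(-math.radians(80), math.radians(80)),
        st.floats(-math.pi + 1e-6, math.pi - 1e-6),
    )
    def test_constructor_matches_scipy_oracle(self, yaw, pitch, roll):
        q = quaternion_from_euler(EulerAngles(yaw, pitch, roll))
        ref = Rotation.from_euler("ZYX", [yaw, pitch, roll]).as_quat()  # x,y,z,w
        ours = np.array([q.q1, q.q2, q.q3, q.q0])
        if np.dot(ours, ref) < 0:
            ref = -ref
        assert np.allclose(ours, ref, atol=1e-9)

    def test_pitch_argument_clamped_at_gimbal_pole(self):
        q = quaternion_from_euler(EulerAngles(0.0, math.pi / 2, 0.0))
        e = euler_from_quaternion(q)
        assert e.pitch == pytest.approx(math.pi / 2, abs=1e-7)


class TestConvergenceOnSimulatedData:
    def test_static_tilt_recovered_within_one_degree(self):
        tilt = math.radians(30.0)
        spec = TrajectorySpec(
            roll=lambda t: tilt,
            duration=10.0,
            dt=0.01,
            gyro_noise_sd=0.002,
            seed=7,
        )
        stream, _ = generate_imu_trajectory(spec)
        gains = FusionGains(kp=2.0, ki=0.005, half_t=spec.dt / 2)
        _, eulers = solve_stream(stream, gains)
        assert math.degrees(abs(eulers[-1].roll - tilt)) < 1.0

    def test_dynamic_trajectory_rms_below_one_degree(self):
        spec = TrajectorySpec(
            yaw=lambda t: math.radians(10.0) * t,
            roll=lambda t: math.radians(15.0) * math.sin(0.5 * t),
            yaw_rate=lambda t: math.radians(10.0),
            roll_rate=lambda t: math.radians(7.5) * math.cos(0.5 * t),
            pitch_rate=lambda t: 0.0,
            duration=30.0,
            dt=0.02,
            gyro_noise_sd=0.01,
            accel_noise_sd=0.01,
            seed=11,
        )
        stream, truth = generate_imu_trajectory(spec)
        _, eulers = solve_stream(stream, FusionGains(kp=2.0, ki=0.005, half_t=spec.dt / 2))
        def wrap(d):  # truth yaw is unwrapped; compare on the circle
            return (d + math.pi) % (2 * math.pi) - math.pi

        burn = 250
        errs = []
        for est, ref in zip(eulers[burn:], truth[burn:]):
            errs.extend(
                [wrap(est.yaw - ref.yaw), wrap(est.pitch - ref.pitch), wrap(est.roll - ref.roll)]
            )
        rms = math.degrees(float(np.sqrt(np.mean(np.square(errs)))))
        assert rms < 1.0


def test_invalid_gains_rejected():
    with pytest.raises(ValidationError):
        FusionGains(kp=-1.0)
    with pytest.raises(ValidationError):
        FusionGains(half_t=0.0)
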