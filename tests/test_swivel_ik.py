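"""Augmented Jacobian, damped least squares and closed-loop tracking."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from arm7ik import (
    IKConfig,
    IKState,
    RigidTransform,
    SessionRecording,
    augmented_jacobian,
    damped_pseudoinverse,
    forward_kinematics,
    geometric_jacobian,
    ik_step,
    joint_points,
    pose_error,
    reconstruct_trajectory,
    swivel_angle,
    swivel_jacobian,
)
from arm7ik.elbow_from_accel import DegenerateGeometryError
from arm7ik.swivel_ik import swivel_reference_axis
from arm7ik.synthetic import accelerometer_sample
from arm7ik.transforms import rotation_about_axis

from conftest import random_interior_q

REF_AXIS = np.array([0.0, -1.0, 0.0])  # gravity in the default mounting


def _fd_geometric_jacobian(q, geom, h=1e-7):
    J = np.empty((6, 7))
    for i in range(7):
        qp, qm = q.copy(), q.copy()
        qp[i] += h
        qm[i] -= h
        Tp = forward_kinematics(qp, geom)[6]
        Tm = forward_kinematics(qm, geom)[6]
        J[:3, i] = (Tp.position - Tm.position) / (2 * h)
        J[3:, i] = Rotation.from_matrix(Tp.rotation @ Tm.rotation.T).as_rotvec() / (2 * h)
    return J


def test_geometric_jacobian_matches_finite_differences(geom, rng):
    worst = 0.0
    for q in random_interior_q(rng, 25):
        J = geometric_jacobian(q, geom)
        worst = max(worst, np.abs(J - _fd_geometric_jacobian(q, geom)).max())
    assert worst < 1e-6


def test_geometric_jacobian_rank_and_wrist_columns(geom, rng):
    q = random_interior_q(rng)
    J = geometric_jacobian(q, geom)
    assert np.linalg.matrix_rank(J, tol=1e-8) == 6
    # the hand point lies on the axes of the three wrist joints
    np.testing.assert_allclose(J[:3, 4:], 0.0, atol=1e-12)


class TestSwivelAngle:
    def test_elbow_in_reference_plane_gives_zero(self, geom):
        S = np.zeros(3)
        W = np.array([0.4, -0.2, 0.0])
        # elbow in the plane spanned by S->W and the reference axis
        E = 0.5 * W + 0.1 * REF_AXIS
        assert swivel_angle(S, E, W, REF_AXIS) == pytest.approx(0.0, abs=1e-12)

    def test_rotation_about_axis_shifts_angle(self, rng):
        S = np.zeros(3)
        W = np.array([0.3, -0.3, 0.1])
        E = np.array([0.1, -0.25, 0.05])
        axis = W / np.linalg.norm(W)
        a0 = swivel_angle(S, E, W, REF_AXIS)
        for delta in rng.uniform(-2.5, 2.5, 10):
            E2 = rotation_about_axis(axis, delta) @ E
            shifted = swivel_angle(S, E2, W, REF_AXIS)
            diff = (shifted - a0 - delta + np.pi) % (2 * np.pi) - np.pi
            assert abs(diff) < 1e-10

    def test_degenerate_geometry_raises(self):
        S = np.zeros(3)
        with pytest.raises(DegenerateGeometryError):
            swivel_angle(S, np.array([0.1, 0, 0]), S, REF_AXIS)
        W = np.array([0.5, 0, 0])
        with pytest.raises(DegenerateGeometryError):
            swivel_angle(S, 0.4 * W, W, REF_AXIS)
        with pytest.raises(DegenerateGeometryError):
            swivel_angle(S, np.array([0.1, -0.2, 0.0]), -0.5 * REF_AXIS, REF_AXIS)


def test_swivel_jacobian_matches_finite_differences(geom, rng):
    h = 1e-5
    for q in random_interior_q(rng, 10):
        row = swivel_jacobian(q, geom, REF_AXIS)
        assert np.all(row[0, 4:] == 0.0)
        for i in range(7):
            qp, qm = q.copy(), q.copy()
            qp[i] += h
            qm[i] -= h
            fd = (
                swivel_angle(*joint_points(qp, geom), REF_AXIS)
                - swivel_angle(*joint_points(qm, geom), REF_AXIS)
            ) / (2 * h)
            assert row[0, i] == pytest.approx(fd, abs=1e-6)


def test_swivel_rate_prediction_on_slow_trajectory(geom):
    """J_alpha q_dot reproduces the discrete swivel rate of a smooth motion."""
    t = np.arange(0.0, 2.0, 0.01)
    q0 = np.array([0.3, -0.3, 0.2, 0.5, 0.1, -0.1, 0.1])
    qdot = np.array([0.1, -0.05, 0.08, 0.12, 0.0, 0.0, 0.0])
    alphas = []
    for tk in t:
        alphas.append(swivel_angle(*joint_points(q0 + qdot * tk, geom), REF_AXIS))
    discrete = np.diff(alphas) / 0.01
    for k in range(0, len(t) - 1, 20):
        predicted = float((swivel_jacobian(q0 + qdot * t[k], geom, REF_AXIS) @ qdot)[0])
        assert predicted == pytest.approx(discrete[k], abs=1e-3)


def test_augmented_jacobian_stacking_and_invertibility(geom, rng):
    q = random_interior_q(rng)
    aug = augmented_jacobian(q, geom, REF_AXIS)
    assert aug.J_A.shape == (7, 7)
    np.testing.assert_array_equal(aug.J_A[:6], aug.J_g)
    np.testing.assert_array_equal(aug.J_A[6:], aug.J_alpha)
    np.testing.assert_array_equal(aug.J_g, geometric_jacobian(q, geom))
    assert abs(np.linalg.det(aug.J_A)) > 1e-12


class TestDampedPseudoinverse:
    def test_identity_closed_form(self):
        np.testing.assert_allclose(damped_pseudoinverse(np.eye(7), 0.5), np.eye(7) / 1.5, atol=1e-14)

    def test_zero_damping_is_exact_inverse(self, rng):
        J = rng.normal(size=(7, 7)) + 3 * np.eye(7)
        np.testing.assert_allclose(damped_pseudoinverse(J, 0.0), np.linalg.inv(J), atol=1e-10)

    def test_singular_bounded_by_damping(self, rng):
        J = np.diag([2.0, 1.0, 0.5, 0.1, 1e-8, 0.0, 0.3])
        k2 = 0.5
        Js = damped_pseudoinverse(J, k2)
        assert np.all(np.isfinite(Js))
        # every damped singular value sigma/(sigma^2+k2) <= 1/(2 sqrt(k2))
        assert np.linalg.svd(Js)[1].max() <= 1 / (2 * np.sqrt(k2)) + 1e-12

    def test_convergence_to_inverse_as_damping_vanishes(self, rng):
        J = rng.normal(size=(7, 7)) + 3 * np.eye(7)
        assert np.abs(damped_pseudoinverse(J, 1e-12) - np.linalg.inv(J)).max() < 1e-8

    def test_singular_with_zero_damping_raises(self):
        J = np.diag([1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.0])
        with pytest.raises(np.linalg.LinAlgError):
            damped_pseudoinverse(J, 0.0)


class TestPoseError:
    def test_zero_for_identical_poses(self):
        T = RigidTransform(np.eye(3), np.array([0.1, 0.2, 0.3]))
        np.testing.assert_array_equal(pose_error(T, T, 0.3, 0.3), np.zeros(7))

    def test_pure_translation(self):
        a = RigidTransform(np.eye(3), np.zeros(3))
        b = RigidTransform(np.eye(3), np.array([0.01, 0.0, 0.0]))
        np.testing.assert_allclose(pose_error(a, b, 0.0, 0.0), [0.01, 0, 0, 0, 0, 0, 0], atol=1e-15)

    def test_small_rotation_is_axis_angle(self):
        delta = 1e-3
        b = RigidTransform(rotation_about_axis(np.array([0.0, 0, 1]), delta), np.zeros(3))
        err = pose_error(RigidTransform(), b, 0.0, 0.0)
        np.testing.assert_allclose(err[3:6], [0.0, 0.0, delta], atol=delta**3)

    def test_swivel_wrapping(self):
        T = RigidTransform()
        err = pose_error(T, T, -np.pi + 0.1, np.pi - 0.1)
        assert err[6] == pytest.approx(-0.2, abs=1e-12)


class TestIKStep:
    def test_fixed_point_at_target(self, geom, ik_cfg):
        q = np.array([0.3, -0.3, 0.2, 0.5, 0.1, -0.1, 0.1])
        target = forward_kinematics(q, geom)[6]
        alpha = swivel_angle(*joint_points(q, geom), swivel_reference_axis(ik_cfg, geom))
        out = ik_step(IKState(q), target, alpha, np.zeros(6), 0.0, ik_cfg, geom)
        np.testing.assert_allclose(out.q, q, atol=1e-12)

    def test_step_contracts_pose_error(self, geom, ik_cfg):
        q = np.array([0.3, -0.3, 0.2, 0.5, 0.1, -0.1, 0.1])
        ref = swivel_reference_axis(ik_cfg, geom)
        q_target = q + 0.02
        target = forward_kinematics(q_target, geom)[6]
        alpha_t = swivel_angle(*joint_points(q_target, geom), ref)

        def err_norm(qq):
            cur = forward_kinematics(qq, geom)[6]
            a = swivel_angle(*joint_points(qq, geom), ref)
            return np.linalg.norm(pose_error(cur, target, a, alpha_t))

        out = ik_step(IKState(q), target, alpha_t, np.zeros(6), 0.0, ik_cfg, geom)
        assert err_norm(out.q) < err_norm(q)

    def test_static_target_converges(self, geom, ik_cfg):
        """Closed loop drives the steady-state pose error below 1e-4 m."""
        q = np.array([0.3, -0.3, 0.2, 0.5, 0.1, -0.1, 0.1])
        ref = swivel_reference_axis(ik_cfg, geom)
        q_target = q + 0.05
        target = forward_kinematics(q_target, geom)[6]
        alpha_t = swivel_angle(*joint_points(q_target, geom), ref)
        state = IKState(q)
        for _ in range(800):
            state = ik_step(state, target, alpha_t, np.zeros(6), 0.0, ik_cfg, geom)
        cur = forward_kinematics(state.q, geom)[6]
        a = swivel_angle(*joint_points(state.q, geom), ref)
        assert np.linalg.norm(pose_error(cur, target, a, alpha_t)) < 1e-4

    def test_non_finite_inputs_raise(self, geom, ik_cfg):
        with pytest.raises(ValueError):
            ik_step(IKState(np.zeros(7)), RigidTransform(), 0.0, np.full(6, np.nan), 0.0, ik_cfg, geom)


class TestReconstruction:
    def test_constant_recording_gives_constant_joints(self, geom, ik_cfg):
        q = np.array([0.3, -0.3, 0.2, 0.5, 0.1, -0.1, 0.1])
        frames = forward_kinematics(q, geom)
        n = 50
        rec = SessionRecording(
            np.arange(n) * 0.01,
            np.tile(frames[6].rotation, (n, 1, 1)),
            np.tile(frames[6].position, (n, 1)),
            np.tile(accelerometer_sample(q, geom), (n, 1)),
            np.tile(geom.shoulder_position, (n, 1)),
        )
        res = reconstruct_trajectory(rec, geom, ik_cfg, q)
        np.testing.assert_allclose(res.q, np.tile(q, (n, 1)), atol=1e-10)

    def test_noiseless_session_recovers_joints(self, geom, ik_cfg, short_session):
        rec, q_true, q0 = short_session
        res = reconstruct_trajectory(rec, geom, ik_cfg, q0)
        rmse = np.degrees(np.sqrt(np.mean((res.q - q_true) ** 2, axis=0)))
        assert rmse.max() < 0.5
        assert np.all(res.condition_number[1:] < 1e6)

    def test_nan_sample_skipped_with_warning(self, geom, ik_cfg, short_session):
        rec, _, q0 = short_session
        accel = rec.accel.copy()
        accel[100] = np.nan
        broken = SessionRecording(rec.t, rec.ee_rotations, rec.ee_positions, accel, rec.shoulder, rec.q_true)
        with pytest.warns(UserWarning, match="skipping 1"):
            res = reconstruct_trajectory(broken, geom, ik_cfg, q0)
        assert len(res.q) == len(rec) - 1
        assert res.n_skipped == 1

    def test_nan_sample_aborts_when_configured(self, geom, short_session):
        rec, _, q0 = short_session
        accel = rec.accel.copy()
        accel[100] = np.nan
        broken = SessionRecording(rec.t, rec.ee_rotations, rec.ee_positions, accel, rec.shoulder, rec.q_true)
        cfg = IKConfig(nan_policy="abort")
        with pytest.raises(ValueError, match="non-finite"):
            reconstruct_trajectory(broken, geom, cfg, q0)
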