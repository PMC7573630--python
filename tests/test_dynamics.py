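import numpy as np
import pytest

from runopt3d import (forward_kinematics, multibody_residual, full_dynamics_residual,
                      forward_dynamics, energy, contact_generalized_forces)
from runopt3d.dynamics import residual_jacobians, residual_jacobians_dense

G = 9.81


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------

def test_neutral_pose_axis_aligned(runner):
    q = np.zeros(21)
    q[runner.dof_index["pelvis_ty"]] = 1.05
    kin = forward_kinematics(runner, q, np.zeros(21))
    for name, (R, o) in kin.segment_poses.items():
        np.testing.assert_allclose(R, np.eye(3), atol=1e-12)
    # heel x position equals its chain offset; both feet symmetric in z
    heel_r = kin.contact_positions["foot_r"][0]
    heel_l = kin.contact_positions["foot_l"][0]
    assert heel_r[0] == pytest.approx(heel_l[0])
    assert heel_r[2] == pytest.approx(-heel_l[2])


def test_translation_invariance(runner):
    rng = np.random.default_rng(3)
    q = rng.normal(0, 0.3, 21)
    q[runner.dof_index["pelvis_ty"]] = 1.0
    kin0 = forward_kinematics(runner, q, np.zeros(21))
    q2 = q.copy()
    q2[runner.dof_index["pelvis_tx"]] += 1.0
    kin1 = forward_kinematics(runner, q2, np.zeros(21))
    for seg in kin0.contact_positions:
        for p0, p1 in zip(kin0.contact_positions[seg], kin1.contact_positions[seg]):
            np.testing.assert_allclose(p1 - p0, [1.0, 0.0, 0.0], atol=1e-12)


def test_heading_rotation_maps_forward_to_right():
    # rotation by +pi/2 about the vertical maps +x to -z (right-handed, y up)
    from runopt3d import build_reduced_runner
    m = build_reduced_runner()
    q = np.zeros(21)
    q[m.dof_index["pelvis_rot"]] = np.pi / 2
    kin = forward_kinematics(m, q, np.zeros(21))
    R, _ = kin.segment_poses["pelvis"]
    np.testing.assert_allclose(R @ [1, 0, 0], [0, 0, -1], atol=1e-12)


def test_point_velocity_consistent_with_position_derivative(runner):
    rng = np.random.default_rng(5)
    q = rng.normal(0, 0.3, 21)
    qd = rng.normal(0, 1.0, 21)
    kin = forward_kinematics(runner, q, qd)
    dt = 1e-7
    kin2 = forward_kinematics(runner, q + dt * qd, qd)
    for seg in kin.contact_positions:
        for p0, p1, v in zip(kin.contact_positions[seg], kin2.contact_positions[seg],
                             kin.contact_velocities[seg]):
            np.testing.assert_allclose((p1 - p0) / dt, v, rtol=1e-5, atol=1e-5)


def test_nan_in_q_names_offending_dof(runner):
    q = np.zeros(21)
    q[runner.dof_index["knee_angle_l"]] = np.nan
    with pytest.raises(ValueError, match="knee_angle_l"):
        forward_kinematics(runner, q, np.zeros(21))


def test_rotations_orthonormal(runner):
    rng = np.random.default_rng(11)
    q = rng.normal(0, 0.5, 21)
    kin = forward_kinematics(runner, q, np.zeros(21))
    for name, (R, _) in kin.segment_poses.items():
        assert np.linalg.norm(R.T @ R - np.eye(3)) < 1e-10


# ---------------------------------------------------------------------------
# multibody residual
# ---------------------------------------------------------------------------

def test_pendulum_closed_form(pendulum):
    # uniform rod, pin at end: qdd = -(3 g / 2 L) sin(q)
    for q in np.linspace(-3, 3, 13):
        qdd = -1.5 * G * np.sin(q)
        r = multibody_residual(pendulum, [q], [0.0], [qdd], [0.0])
        assert abs(r[0]) < 1e-10


def test_pendulum_example_value(pendulum):
    # q = pi/2: qdd = -3g/(2L) = -14.715 rad/s^2
    qdd = forward_dynamics(pendulum, [np.pi / 2], [0.0], [0.0])
    assert qdd[0] == pytest.approx(-14.715, abs=1e-9)


def test_free_fall(runner):
    q = np.zeros(21)
    q[runner.dof_index["pelvis_ty"]] = 30.0  # far above ground, no contact
    qdd = np.zeros(21)
    qdd[runner.dof_index["pelvis_ty"]] = -G
    r = multibody_residual(runner, q, np.zeros(21), qdd, np.zeros(21))
    np.testing.assert_allclose(r, 0.0, atol=1e-9)


def test_residual_affine_in_qdd(runner):
    rng = np.random.default_rng(7)
    q = rng.normal(0, 0.3, 21)
    qd = rng.normal(0, 1.0, 21)
    a1 = rng.normal(0, 5, 21)
    a2 = rng.normal(0, 5, 21)
    t = np.zeros(21)
    r = lambda a: multibody_residual(runner, q, qd, a, t)
    np.testing.assert_allclose(r(a1 + a2) - r(a1) - r(a2) + r(np.zeros(21)),
                               0.0, atol=1e-7)


def test_energy_conserved_passive_pendulum(pendulum):
    y = np.array([1.2, 0.0])
    h = 1e-3

    def f(y):
        return np.array([y[1], forward_dynamics(pendulum, [y[0]], [y[1]], [0.0])[0]])

    E0 = energy(pendulum, [y[0]], [y[1]])
    for _ in range(400):
        k1 = f(y); k2 = f(y + h / 2 * k1); k3 = f(y + h / 2 * k2); k4 = f(y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    assert abs(energy(pendulum, [y[0]], [y[1]]) - E0) < 1e-8


# ---------------------------------------------------------------------------
# full residual and Jacobians
# ---------------------------------------------------------------------------

def test_activation_rows_vanish_at_steady_state(runner):
    lay = runner.layout
    rng = np.random.default_rng(2)
    x = np.zeros(lay.n_x)
    x[runner.dof_index["pelvis_ty"]] = 1.0
    x[lay.s] = [mu.params.l_CE_opt for mu in runner.muscles]
    a = rng.uniform(0.1, 0.9, lay.n_mus)
    x[lay.a] = a
    u = np.zeros(lay.n_u)
    u[:lay.n_mus] = a  # n_e = a, adot = 0 -> activation rows zero
    r = full_dynamics_residual(runner, x, np.zeros(lay.n_x), u)
    np.testing.assert_allclose(r[2 * lay.n_dof + lay.n_mus:], 0.0, atol=1e-14)


def test_layout_mismatch_raises(runner):
    with pytest.raises(ValueError, match="layout"):
        full_dynamics_residual(runner, np.zeros(10), np.zeros(10), np.zeros(3))


def test_jacobians_match_finite_differences(runner, rand_state):
    random_state = rand_state
    rng = np.random.default_rng(12)
    lay = runner.layout
    worst = 0.0
    for _ in range(3):
        x, xd, u = random_state(runner, rng)
        Jx, Jxd, Ju = residual_jacobians_dense(runner, x, xd, u)
        scale = max(1.0, np.abs(Jx).max(), np.abs(Jxd).max(), np.abs(Ju).max())
        hstep = 1e-6
        for J, arg in ((Jx, 0), (Jxd, 1), (Ju, 2)):
            vecs = (x, xd, u)
            n = len(vecs[arg])
            for i in range(0, n, 9):
                vp = [v.copy() for v in vecs]
                vm = [v.copy() for v in vecs]
                vp[arg][i] += hstep
                vm[arg][i] -= hstep
                fd = (full_dynamics_residual(runner, *vp) -
                      full_dynamics_residual(runner, *vm)) / (2 * hstep)
                worst = max(worst, float(np.abs(fd - J[:, i]).max() / scale))
    assert worst < 1e-5


def test_sparsity_pattern_stable_across_points(runner, rand_state):
    random_state = rand_state
    rng = np.random.default_rng(4)
    patterns = []
    for _ in range(3):
        x, xd, u = random_state(runner, rng)
        jac = residual_jacobians(runner, x, xd, u)
        patterns.append((jac.dfdx.indptr.tobytes(), jac.dfdx.indices.tobytes(),
                         jac.dfdxd.indices.tobytes(), jac.dfdu.indices.tobytes()))
    assert patterns[0] == patterns[1] == patterns[2]


def test_dfdxd_kinematic_identity_block(runner, rand_state):
    x, xd, u = rand_state(runner, np.random.default_rng(9))
    jac = residual_jacobians(runner, x, xd, u)
    blk = jac.dfdxd.toarray()[:21, :21]
    np.testing.assert_allclose(blk, np.eye(21), atol=1e-12)


def test_fast_block_jacobian_matches_full_complex_step(runner, rand_state):
    from runopt3d.dynamics import residual_block_jacobians
    random_state = rand_state
    rng = np.random.default_rng(21)
    x, xd, u = random_state(runner, rng)
    dfdx, dfdxd, dfdu = residual_block_jacobians(runner, x[None], xd[None], u[None])
    Jx, Jxd, Ju = residual_jacobians_dense(runner, x, xd, u)
    np.testing.assert_allclose(dfdx[0], Jx, atol=1e-10)
    np.testing.assert_allclose(dfdxd[0], Jxd, atol=1e-10)
    np.testing.assert_allclose(dfdu[0], Ju, atol=1e-10)


def test_contact_generalized_forces_zero_without_contact(runner):
    q = np.zeros(21)
    q[runner.dof_index["pelvis_ty"]] = 30.0
    tau, grfs = contact_generalized_forces(runner, q, np.zeros(21))
    np.testing.assert_allclose(tau, 0.0, atol=1e-6)
    for g in grfs.values():
        np.testing.assert_allclose(g, 0.0, atol=1e-6)
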