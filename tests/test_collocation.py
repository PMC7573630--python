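import numpy as np
import pytest

from runopt3d import (ObjectiveConfig, PeriodicityMap, backward_euler_defects,
                      central_angle, periodicity_residual, assemble_nlp,
                      check_derivatives, solve, SolverSettings, TaskSpec,
                      build_reduced_runner, synth_reference, cycles_to_reference)
from runopt3d.tasks import tracked_signals


# ---------------------------------------------------------------------------
# central angle
# ---------------------------------------------------------------------------

def test_central_angle_values():
    assert central_angle(0.0, 0.7, 3.7)[0] == 0.0
    # chord equal to the diameter subtends pi
    assert central_angle(2.0, 3.7, 3.7)[0] == pytest.approx(np.pi)
    # curved-running study parameters: theta = 2 asin(2.7*0.74/7.4)
    th, _ = central_angle(2.7, 0.74, 3.7)
    assert th == pytest.approx(2 * np.arcsin(0.27), abs=1e-12)
    assert th == pytest.approx(0.5468, abs=2e-4)


def test_central_angle_infeasible_chord():
    with pytest.raises(ValueError, match="diameter"):
        central_angle(3.0, 3.0, 1.0)


def test_central_angle_monotone_and_small_T_limit():
    v, r = 2.7, 3.7
    Ts = np.linspace(0.05, 1.2, 40)
    th = np.array([central_angle(v, T, r)[0] for T in Ts])
    assert np.all(np.diff(th) > 0)
    T = 1e-3
    assert central_angle(v, T, r)[0] == pytest.approx(v * T / r, rel=1e-6)


def test_central_angle_derivative_matches_fd():
    v, r, T = 2.7, 3.7, 0.7
    th, dth = central_angle(v, T, r)
    h = 1e-7
    fd = (central_angle(v, T + h, r)[0] - central_angle(v, T - h, r)[0]) / (2 * h)
    assert dth == pytest.approx(fd, rel=1e-6)


# ---------------------------------------------------------------------------
# periodicity map
# ---------------------------------------------------------------------------

def test_identity_map_is_identity(runner):
    pm = PeriodicityMap()
    x = np.random.default_rng(0).normal(size=78)
    np.testing.assert_array_equal(pm.apply(x, 0.7), x)


def test_straight_map_reduces_to_translation(runner):
    pm = PeriodicityMap.straight(runner, 4.0, 0.0)
    x = np.zeros(78)
    out = pm.apply(x, 0.7)
    di = runner.dof_index
    assert out[di["pelvis_tx"]] == pytest.approx(2.8)
    assert out[di["pelvis_ty"]] == 0.0
    out[di["pelvis_tx"]] = 0.0
    np.testing.assert_array_equal(out, x)


def test_curved_map_quarter_circle(runner):
    # theta = pi/2: start (-3.7, .95, 0) heading 0 -> (0, .95, 3.7) heading pi/2
    r, T = 3.7, 0.74
    v = 2 * r * np.sin(np.pi / 4) / T
    pm = PeriodicityMap.curved(runner, v, r)
    di = runner.dof_index
    x = np.zeros(78)
    x[di["pelvis_tx"]] = -3.7
    x[di["pelvis_ty"]] = 0.95
    out = pm.apply(x, T)
    assert out[di["pelvis_tx"]] == pytest.approx(0.0, abs=1e-12)
    assert out[di["pelvis_ty"]] == pytest.approx(0.95)
    assert out[di["pelvis_tz"]] == pytest.approx(3.7)
    assert out[di["pelvis_rot"]] == pytest.approx(np.pi / 2)


def test_periodicity_residual_zero_for_identity(runner):
    pm = PeriodicityMap()
    rng = np.random.default_rng(1)
    x = rng.normal(size=78)
    u = rng.normal(size=21)
    r = periodicity_residual(x, x, u, u, pm, 0.7)
    np.testing.assert_allclose(r, 0.0, atol=1e-14)


def test_periodicity_map_jacobian_matches_complex_step(runner):
    rng = np.random.default_rng(2)
    x0 = rng.normal(size=78)
    T = 0.71
    for pm in (PeriodicityMap.straight(runner, 4.0, 0.3),
               PeriodicityMap.curved(runner, 2.7, 3.7)):
        DP, dPdT = pm.jacobian(x0, T)
        h = 1e-30
        for j in range(0, 78, 11):
            xc = x0.astype(complex)
            xc[j] += 1j * h
            col = pm.apply(xc, T).imag / h
            np.testing.assert_allclose(DP[:, j], col, atol=1e-12)
        col_T = pm.apply(x0.astype(complex), T + 1j * h).imag / h
        np.testing.assert_allclose(dPdT, col_T, atol=1e-9)


# ---------------------------------------------------------------------------
# backward-Euler defects
# ---------------------------------------------------------------------------

def test_scalar_ode_backward_euler_step():
    # xdot = -x, h = 0.1: defect zero iff x1 = x0 / 1.1
    fn = lambda Xk, Xd, Uk: Xd + Xk
    X = np.array([[1.0], [1.0 / 1.1]])
    U = np.zeros((2, 1))
    d = backward_euler_defects(fn, X, U, 0.2, None)
    assert abs(d[0, 0]) < 1e-12
    X_bad = np.array([[1.0], [0.95]])
    assert abs(backward_euler_defects(fn, X_bad, U, 0.2, None)[0, 0]) > 1e-3


def test_wrap_defect_uses_periodicity_image(runner):
    pm = PeriodicityMap.straight(runner, 4.0, 0.0)
    recorded = {}

    def fn(Xk, Xd, Uk):
        recorded["Xk"] = Xk
        return np.zeros_like(Xk)

    rng = np.random.default_rng(3)
    X = rng.normal(size=(5, 78))
    U = rng.normal(size=(5, 21))
    backward_euler_defects(fn, X, U, 0.7, pm)
    np.testing.assert_allclose(recorded["Xk"][-1], pm.apply(X[0], 0.7))


# ---------------------------------------------------------------------------
# NLP assembly / solving
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_nlp(runner):
    ref = cycles_to_reference(synth_reference(runner, speed=4.0, n_cycles=12, seed=1), 4)
    config = ObjectiveConfig(W_mus=1e3, v_ref=(4.0, 0.0))
    task = TaskSpec(kind="straight", v_x=4.0, N=4, config=config,
                    tracked=tracked_signals(runner, "straight"),
                    anchors={"pelvis_tx": 0.0, "pelvis_tz": 0.0})
    return assemble_nlp(runner, task, config, ref)


def _feasible_point(nlp, seed=0):
    rng = np.random.default_rng(seed)
    lo = np.maximum(nlp.lb, -3.0)
    hi = np.minimum(nlp.ub, 3.0)
    z = lo + (hi - lo) * rng.uniform(0.3, 0.7, nlp.n_var)
    z[nlp.iT] = 0.7
    return np.clip(z, nlp.lb, nlp.ub)


def test_anchor_bounds_pin_first_node(small_nlp):
    di = small_nlp.model.dof_index
    assert small_nlp.lb[di["pelvis_tx"]] == small_nlp.ub[di["pelvis_tx"]] == 0.0
    assert small_nlp.lb[di["pelvis_tz"]] == small_nlp.ub[di["pelvis_tz"]] == 0.0


def test_constraint_jacobian_matches_finite_differences(small_nlp):
    z = _feasible_point(small_nlp)
    rep = check_derivatives(small_nlp, z, seed=0, n_dirs=50)
    assert rep["jac_max_rel_error"] < 1e-5
    assert rep["grad_max_rel_error"] < 1e-5


def test_check_derivatives_flags_corruption(small_nlp):
    z = _feasible_point(small_nlp, seed=1)
    orig = small_nlp.ls_jac
    col = 5

    def corrupted(zz):
        J = orig(zz).tolil()
        J[0, col] += 1e6
        return J.tocsr()

    small_nlp.ls_jac = corrupted
    try:
        rep = check_derivatives(small_nlp, z, seed=0, n_dirs=None)
        assert rep["grad_max_rel_error"] > 1e-4
    finally:
        small_nlp.ls_jac = orig


def test_objective_value_is_weighted_term_sum(small_nlp):
    z = _feasible_point(small_nlp, seed=2)
    J = small_nlp.objective_value(z)
    total, terms = small_nlp.breakdown(z)
    assert J == pytest.approx(total, rel=1e-9)


def test_solve_rejects_infeasible_bounds(small_nlp):
    lb = small_nlp.lb.copy()
    try:
        small_nlp.lb = small_nlp.ub + 1.0
        with pytest.raises(ValueError, match="bounds"):
            solve(small_nlp, np.zeros(small_nlp.n_var))
    finally:
        small_nlp.lb = lb


def test_missing_reference_for_tracking_task(runner):
    config = ObjectiveConfig()
    task = TaskSpec(kind="straight", v_x=4.0, N=4, config=config,
                    tracked=tracked_signals(runner, "straight"))
    with pytest.raises(ValueError):
        assemble_nlp(runner, task, config, None)


def test_qp_smoke_recovers_analytic_optimum():
    """Equality-constrained convex QP through the AL Gauss-Newton machinery.

    min 0.5 ||z - c||^2 s.t. z0 + z1 = 1; optimum is the projection of c
    onto the constraint plane.
    """
    from runopt3d.collocation import _solve_al_gn
    import scipy.sparse as sp

    c = np.array([2.0, -1.0, 0.5])

    class QP:
        n_var = 3
        n_con = 1
        lb = np.full(3, -10.0)
        ub = np.full(3, 10.0)
        kind = "qp"

        def ls_residuals(self, z):
            return z - c

        def ls_jac(self, z):
            return sp.eye(3, format="csr")

        def constraints(self, z):
            return np.array([z[0] + z[1] - 1.0])

        def constraints_jac(self, z):
            return sp.csr_matrix(np.array([[1.0, 1.0, 0.0]]))

    qp = QP()
    z, _, _ = _solve_al_gn(qp, np.zeros(3), SolverSettings(
        penalty_stages=(10.0, 100.0), al_updates=8, max_nfev_stage=50,
        lm_iters=30, feas_rounds=0, ctol=1e-9), [])
    lam = (c[0] + c[1] - 1.0) / 2.0
    z_star = np.array([c[0] - lam, c[1] - lam, c[2]])
    np.testing.assert_allclose(z, z_star, atol=1e-6)
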