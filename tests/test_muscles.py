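import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from runopt3d import (MuscleParameters, PathPolynomial, mtu_geometry,
                      fit_path_polynomial, contraction_residual, activation_residual)
from runopt3d.muscles import force_length, force_velocity, tendon_force


@pytest.fixture(scope="module")
def p():
    return MuscleParameters("test", F_ISO=1000.0, l_CE_opt=0.1, l_slack=0.2)


# ---------------------------------------------------------------------------
# path geometry
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("terms,q,l_exp,arm_exp", [
    # linear path l = 0.4 - 0.05 q: at q=0 length 0.4, arm +0.05
    ([((0,), 0.4), ((1,), -0.05)], [0.0], 0.4, [0.05]),
    # constant path: zero moment arm
    ([((0,), 0.3)], [0.7], 0.3, [0.0]),
    # quadratic: l(0.5) = 0.4 - 0.025 + 0.0025 = 0.3775, arm = -(-0.05 + 0.01) = 0.04
    ([((0,), 0.4), ((1,), -0.05), ((2,), 0.01)], [0.5], 0.3775, [0.04]),
])
def test_mtu_geometry_examples(terms, q, l_exp, arm_exp):
    path = PathPolynomial(("knee",), terms)
    l, arms = mtu_geometry(path, np.asarray(q))
    assert l == pytest.approx(l_exp, abs=1e-12)
    np.testing.assert_allclose(arms, arm_exp, atol=1e-12)


def test_moment_arm_equals_negative_length_gradient():
    path = PathPolynomial(("hip", "knee"),
                          [((0, 0), 0.45), ((1, 0), 0.06), ((0, 1), -0.03),
                           ((1, 1), 0.005), ((0, 2), 0.002)])
    rng = np.random.default_rng(0)
    for _ in range(5):
        q = rng.normal(0, 1.0, 2)
        _, arms = mtu_geometry(path, q)
        for j in range(2):
            e = np.zeros(2); e[j] = 1e-6
            fd = (path.length(q + e) - path.length(q - e)) / 2e-6
            assert arms[j] == pytest.approx(-fd, abs=1e-6)


def test_fit_recovers_exact_polynomial():
    true = PathPolynomial(("hip", "knee"),
                          [((0, 0), 0.4), ((1, 0), -0.05), ((0, 1), 0.02),
                           ((2, 1), 0.004), ((0, 3), -0.001)])
    rng = np.random.default_rng(1)
    qs = rng.uniform(-1, 1, (80, 2))
    samples = [(q, float(true.length(q))) for q in qs]
    fitted, rms = fit_path_polynomial(("hip", "knee"), samples, max_degree=3)
    assert rms < 1e-10
    for q in rng.uniform(-1, 1, (10, 2)):
        assert fitted.length(q) == pytest.approx(true.length(q), abs=1e-8)


def test_fit_rank_deficient_raises():
    samples = [(np.array([0.0, 0.0]), 0.4), (np.array([1.0, 0.0]), 0.35)]
    with pytest.raises(ValueError, match="rank"):
        fit_path_polynomial(("hip", "knee"), samples, max_degree=2)


# ---------------------------------------------------------------------------
# Hill dynamics
# ---------------------------------------------------------------------------

def test_isometric_equilibrium_at_optimal_length(p):
    # a=1, s=l_opt, sdot=0, tendon at eps0 strain: F_SEE = F_ISO, residual = 0
    l_mtu = p.l_CE_opt + p.l_slack * (1.0 + p.eps0_SEE)
    r, F = contraction_residual(p, 1.0, p.l_CE_opt, 0.0, l_mtu)
    # the smooth positive-part (strain half-width 1e-4) shifts forces by ~3 ppm
    assert F == pytest.approx(p.F_ISO, rel=1e-5)
    assert abs(r) < 1e-5 * p.F_ISO


def test_slack_tendon_passive_rest(p):
    # slack tendon, no activation, short CE: residual ~ 0
    r, F = contraction_residual(p, 0.0, 0.8 * p.l_CE_opt, 0.0, 0.9 * p.l_CE_opt + p.l_slack - 0.05)
    assert abs(F) < 1e-4 * p.F_ISO
    assert abs(r) < 1e-3 * p.F_ISO


def test_force_velocity_endpoints(p):
    assert force_velocity(p, 0.0) == pytest.approx(1.0)
    assert force_velocity(p, -p.v_max) == pytest.approx(0.0, abs=1e-12)
    assert force_velocity(p, 50.0 * p.v_max) == pytest.approx(p.f_ecc_max, rel=0.02)


def test_max_shortening_kills_active_force(p):
    # at v_CE = -v_max l_opt/s the CE contributes only passive + damping force
    s = p.l_CE_opt
    sdot = -p.v_max * p.l_CE_opt
    l_mtu = s + p.l_slack * (1.0 + p.eps0_SEE)
    r, F_see = contraction_residual(p, 1.0, s, sdot, l_mtu)
    damp = p.d_CE * p.F_ISO * sdot / p.l_CE_opt
    assert r == pytest.approx(F_see - damp, rel=1e-7)


def test_force_length_peak_at_optimum(p):
    assert force_length(p, p.l_CE_opt) == pytest.approx(1.0)
    assert force_length(p, 1.3 * p.l_CE_opt) < 1.0


def test_singularity_freedom_high_pennation():
    pp = MuscleParameters("penn", F_ISO=500.0, l_CE_opt=0.05, l_slack=0.1,
                          phi_opt=1.4)  # near-vertical fibers
    for s in (1e-4, 1e-3, 0.02, 0.1):
        r, F = contraction_residual(pp, 0.7, s, -0.1, 0.16)
        assert np.isfinite(r) and np.isfinite(F)


@settings(max_examples=40, deadline=None)
@given(a=st.floats(0.05, 1.0), s=st.floats(0.06, 0.15), dl=st.floats(-0.01, 0.02))
def test_residual_strictly_monotone_in_sdot(a, s, dl):
    pp = MuscleParameters("m", F_ISO=1000.0, l_CE_opt=0.1, l_slack=0.2)
    l_mtu = s + pp.l_slack + dl
    sd = np.linspace(-1.5, 1.5, 25)
    r = np.array([contraction_residual(pp, a, s, v, l_mtu)[0] for v in sd])
    assert np.all(np.diff(r) < 0.0)


def test_contraction_rejects_nonpositive_s(p):
    with pytest.raises(ValueError):
        contraction_residual(p, 0.5, -0.01, 0.0, 0.3)


@pytest.mark.parametrize("a,adot,ne", [
    (0.5, 0.0, 0.5),          # steady state
    (0.0, 1.0 / 0.01, 1.0),   # pure activation at rate 1/T_act
    (1.0, -1.0 / 0.04, 0.0),  # pure deactivation at rate 1/T_deact
])
def test_activation_dynamics_known_rates(p, a, adot, ne):
    assert activation_residual(p, a, adot, ne) == pytest.approx(0.0, abs=1e-12)


def test_tendon_force_quadratic_above_slack(p):
    l = p.l_slack * (1.0 + p.eps0_SEE) + 0.1
    assert tendon_force(p, l, 0.1) == pytest.approx(p.F_ISO, rel=1e-5)
    # halving the strain quarters the force
    l2 = p.l_slack * (1.0 + 0.5 * p.eps0_SEE) + 0.1
    assert tendon_force(p, l2, 0.1) == pytest.approx(0.25 * p.F_ISO, rel=1e-3)
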