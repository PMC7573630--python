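import numpy as np
import pytest

from runopt3d import (ObjectiveConfig, TrackingReference, adjust_variance,
                      signal_weights, tracking_cost, effort_cost, torque_cost,
                      regularization_cost)
from runopt3d.muscles import MuscleParameters
from runopt3d.model import MuscleRecord, PathPolynomial


def _muscle(F, lopt):
    return MuscleRecord(MuscleParameters("m", F_ISO=F, l_CE_opt=lopt, l_slack=0.2),
                        PathPolynomial(("q",), [((0,), 0.3)]))


# ---------------------------------------------------------------------------
# variance floor
# ---------------------------------------------------------------------------

def test_variance_floor_rule():
    # sd^2 = [0, 1, 2] -> mean variance 1 -> adjusted [0.1, 1, 2]
    sd = np.sqrt([0.0, 1.0, 2.0])
    np.testing.assert_allclose(adjust_variance(sd), [0.1, 1.0, 2.0])


def test_variance_floor_inactive_for_flat_variance():
    np.testing.assert_allclose(adjust_variance(np.ones(5)), np.ones(5))


def test_variance_all_zero_errors():
    with pytest.raises(ValueError):
        adjust_variance(np.zeros(4))


# ---------------------------------------------------------------------------
# signal weights
# ---------------------------------------------------------------------------

def test_signal_weights_paper_values():
    kinds = ["angle"] * 10 + ["grf"] * 6
    w = signal_weights(kinds, W_ang=1.0, W_GRF=5.0)
    np.testing.assert_allclose(w[:10], 1.0 / 40.0)
    np.testing.assert_allclose(w[10:], 5.0 / 40.0)
    assert w.sum() == pytest.approx(1.0)


def test_signal_weights_single_group_uniform():
    w = signal_weights(["angle"] * 7)
    np.testing.assert_allclose(w, 1.0 / 7.0)
    w2 = signal_weights(["angle", "grf"], W_ang=2.0, W_GRF=2.0)
    np.testing.assert_allclose(w2, 0.5)


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

def _ref(n_sig=2, N=10, sd_val=1.0):
    rng = np.random.default_rng(0)
    mean = rng.normal(0, 1, (n_sig, N))
    sd = np.full((n_sig, N), sd_val)
    return TrackingReference([f"s{i}" for i in range(n_sig)], ["angle"] * n_sig, mean, sd)


def test_tracking_zero_at_reference():
    ref = _ref()
    w = signal_weights(ref.kinds)
    assert tracking_cost(ref.mean.T, ref, w, 1.0) == 0.0


def test_tracking_one_sd_offset_gives_unity():
    ref = _ref(n_sig=1)
    y = (ref.mean + ref.sd).T
    assert tracking_cost(y, ref, [1.0], 1.0) == pytest.approx(1.0)


def test_tracking_linear_in_weights():
    ref = _ref()
    rng = np.random.default_rng(1)
    y = ref.mean.T + rng.normal(0, 1, ref.mean.T.shape)
    w = signal_weights(ref.kinds)
    assert tracking_cost(y, ref, 2 * w, 1.0) == pytest.approx(
        2 * tracking_cost(y, ref, w, 1.0))


def test_tracking_invariant_to_signal_order():
    ref = _ref(n_sig=3)
    w = signal_weights(ref.kinds)
    rng = np.random.default_rng(2)
    y = ref.mean.T + rng.normal(0, 0.5, ref.mean.T.shape)
    perm = [2, 0, 1]
    ref_p = ref.subset([ref.names[i] for i in perm])
    assert tracking_cost(y[:, perm], ref_p, w[perm], 1.0) == pytest.approx(
        tracking_cost(y, ref, w, 1.0))


def test_tracking_grid_mismatch_raises():
    ref = _ref()
    with pytest.raises(ValueError, match="grid"):
        tracking_cost(np.zeros((7, 2)), ref, [0.5, 0.5], 1.0)


# ---------------------------------------------------------------------------
# effort / torque / regularization
# ---------------------------------------------------------------------------

def test_effort_two_equal_muscles_hand_value():
    # two equal-volume muscles, n_e = 0.5, |v| = 2: J = 0.5^3 / (2 * 8) = 0.0078125
    muscles = [_muscle(1000, 0.1), _muscle(1000, 0.1)]
    ne = np.full((5, 2), 0.5)
    assert effort_cost(ne, muscles, (2.0, 0.0), 1.0) == pytest.approx(0.0078125)


def test_effort_zero_excitation():
    muscles = [_muscle(1000, 0.1)]
    assert effort_cost(np.zeros((4, 1)), muscles, (2.0, 0.0), 1.0) == 0.0


def test_effort_invariant_to_uniform_strength_scaling():
    rng = np.random.default_rng(3)
    ne = rng.random((6, 3))
    m1 = [_muscle(1000, 0.1), _muscle(2000, 0.08), _muscle(500, 0.12)]
    m10 = [_muscle(10000, 0.1), _muscle(20000, 0.08), _muscle(5000, 0.12)]
    assert effort_cost(ne, m1, (3.0, 0.0), 1.0) == pytest.approx(
        effort_cost(ne, m10, (3.0, 0.0), 1.0))


def test_torque_cost_values():
    assert torque_cost(np.full((8, 3), 0.5), 1.0) == pytest.approx(0.25)
    assert torque_cost(np.zeros((8, 3)), 1.0) == 0.0
    m = np.random.default_rng(0).normal(size=(8, 3))
    assert torque_cost(m, 1.0) == pytest.approx(torque_cost(-m, 1.0))
    assert torque_cost(np.zeros((5, 0)), 1.0) == 0.0


def test_regularization_zero_for_constant_trajectories():
    X = np.ones((10, 4))
    U = np.full((10, 2), 0.3)
    assert regularization_cost(X, U, 0.8) == pytest.approx(0.0)


def test_regularization_sine_state_hand_value():
    N, T = 50, 1.0
    k = np.arange(N)
    x = np.sin(2 * np.pi * k / N)
    X = np.zeros((N, 3))
    X[:, 0] = x
    U = np.zeros((N, 1))
    d = (x - np.roll(x, 1)) / (T / N)
    expected = np.mean(d**2) / 4.0  # 3 states + 1 control
    assert regularization_cost(X, U, T) == pytest.approx(expected)


def test_regularization_quadruples_when_duration_halves():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(12, 3))
    U = rng.normal(size=(12, 2))
    assert regularization_cost(X, U, 0.5) == pytest.approx(
        4.0 * regularization_cost(X, U, 1.0))
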