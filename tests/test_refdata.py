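import numpy as np
import pytest

from runopt3d import (GaitCycleSet, synth_reference, cycles_to_reference,
                      write_sto, read_sto)


def test_generator_deterministic_under_seed(runner):
    a = synth_reference(runner, speed=4.0, n_cycles=5, seed=42)
    b = synth_reference(runner, speed=4.0, n_cycles=5, seed=42)
    assert a.durations == b.durations
    for ca, cb in zip(a.cycles, b.cycles):
        for name in a.names:
            np.testing.assert_array_equal(ca[name], cb[name])


def test_zero_noise_gives_identical_cycles_per_phase(runner):
    g = synth_reference(runner, speed=4.0, n_cycles=3, seed=0,
                        angle_noise_deg=0.0, grf_noise=0.0)
    ref = cycles_to_reference(g, 30)
    np.testing.assert_allclose(ref.sd, 0.0, atol=1e-12)


def test_needs_at_least_two_cycles(runner):
    with pytest.raises(ValueError):
        synth_reference(runner, n_cycles=1)


def test_vertical_impulse_balance(runner):
    # both feet's cycle-averaged vertical GRF equals body weight (92 kg -> 902.5 N)
    g = synth_reference(runner, speed=4.0, n_cycles=12, seed=3)
    ref = cycles_to_reference(g, 200)
    iy = [ref.names.index("grf_r_y"), ref.names.index("grf_l_y")]
    mean_total = ref.mean[iy].sum(axis=0).mean()
    assert mean_total == pytest.approx(runner.weight(), rel=0.01)
    assert runner.weight() == pytest.approx(902.52, abs=0.1)


def test_reference_periodic_within_noise(runner):
    g = synth_reference(runner, speed=4.0, n_cycles=12, seed=1)
    ref = cycles_to_reference(g, 100)
    for i, kind in enumerate(ref.kinds):
        wrap_gap = abs(ref.mean[i, 0] - ref.mean[i, -1])
        scale = max(np.ptp(ref.mean[i]), 1e-9)
        assert wrap_gap < 0.15 * scale + 3 * ref.sd[i].mean()


def test_cycle_averaging_mean_and_sd():
    # two constant cycles valued 1 and 3: mean 2, sample SD sqrt(2)
    cycles = GaitCycleSet(["a"], ["angle"],
                         [{"a": np.full(100, 1.0)}, {"a": np.full(60, 3.0)}],
                         [0.5, 0.3])
    ref = cycles_to_reference(cycles, 50)
    np.testing.assert_allclose(ref.mean[0], 2.0)
    np.testing.assert_allclose(ref.sd[0], np.sqrt(2.0))
    assert ref.n_samples == 50


def test_resampling_to_common_grid_before_averaging():
    ramp_a = {"a": np.linspace(0.0, 1.0, 100, endpoint=False)}
    ramp_b = {"a": np.linspace(0.0, 1.0, 60, endpoint=False)}
    ref = cycles_to_reference(GaitCycleSet(["a"], ["angle"], [ramp_a, ramp_b], [0.5, 0.3]), 50)
    # both cycles carry the same shape in phase, so the SD nearly vanishes
    assert ref.sd.max() < 0.02


def test_cycle_set_requires_all_signals():
    with pytest.raises(ValueError, match="missing"):
        GaitCycleSet(["a", "b"], ["angle", "angle"], [{"a": np.zeros(5)}], [0.4])


def test_averaging_commutes_with_signal_reorder(runner):
    g = synth_reference(runner, speed=4.0, n_cycles=4, seed=2)
    ref = cycles_to_reference(g, 40)
    perm = list(reversed(range(len(g.names))))
    g2 = GaitCycleSet([g.names[i] for i in perm], [g.kinds[i] for i in perm],
                      g.cycles, g.durations)
    ref2 = cycles_to_reference(g2, 40)
    for i, n in enumerate(g2.names):
        np.testing.assert_allclose(ref2.mean[i], ref.mean[ref.names.index(n)])


def test_stance_foot_slip_is_small(runner):
    """The IK-built angle templates keep the loaded foot nearly stationary."""
    from runopt3d.tasks import _seed_kinematics
    from runopt3d.dynamics import get_chain, _FramePass
    N = 48
    ref = cycles_to_reference(synth_reference(runner, speed=4.0, n_cycles=12, seed=1,
                                              angle_noise_deg=0.0, grf_noise=0.0), N)
    lay = runner.layout
    X0 = np.zeros((N, lay.n_x))
    U0 = np.zeros((N, lay.n_u))
    X0[:, runner.dof_index["pelvis_ty"]] = 1.0
    X0[:, lay.s] = 0.1
    t = np.arange(N) * ref.cadence / N
    X0[:, runner.dof_index["pelvis_tx"]] = 4.0 * t
    X0[:, 21 + runner.dof_index["pelvis_tx"]] = 4.0
    _seed_kinematics(runner, X0, U0, ref, ref.cadence)
    chain = get_chain(runner)
    fp = _FramePass(chain, X0[:, :21], X0[:, 21:42])
    ph = np.arange(N) / N
    mid_stance = (ph > 0.06) & (ph < 0.28)
    for elem, local, seg in chain.contacts:
        if seg != "foot_r":
            continue
        _, V = fp.point(chain, elem, local)
        assert np.abs(V[mid_stance, 0]).max() < 1.5  # m/s, vs 4 m/s gait speed


# ---------------------------------------------------------------------------
# motion files
# ---------------------------------------------------------------------------

def test_sto_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    t = np.linspace(0, 0.7, 50)
    cols = {"hip_flexion_r": rng.normal(size=50), "grf_r_y": 1000 * rng.random(50)}
    path = tmp_path / "motion.sto"
    write_sto(path, t, cols)
    t2, cols2, deg = read_sto(path)
    assert not deg
    np.testing.assert_allclose(t2, t, atol=1e-10)
    for k in cols:
        assert np.abs(cols2[k] - cols[k]).max() < 1e-10


def test_sto_degrees_converted_on_read(tmp_path):
    t = np.array([0.0, 0.1])
    path = tmp_path / "deg.sto"
    write_sto(path, t, {"knee_angle_r": np.array([90.0, 45.0]),
                        "grf_r_y": np.array([10.0, 20.0])}, in_degrees=True)
    _, cols, deg = read_sto(path)
    assert deg
    np.testing.assert_allclose(cols["knee_angle_r"], [np.pi / 2, np.pi / 4])
    np.testing.assert_allclose(cols["grf_r_y"], [10.0, 20.0])  # forces untouched


def test_sto_missing_endheader_reports_lines(tmp_path):
    path = tmp_path / "bad.sto"
    path.write_text("name\nnRows=1\nnColumns=2\ntime\tx\n0.0\t1.0\n")
    with pytest.raises(ValueError, match="endheader"):
        read_sto(path)


def test_sto_bad_row_reports_line_number(tmp_path):
    path = tmp_path / "bad2.sto"
    path.write_text("m\nnRows=2\nnColumns=2\ninDegrees=no\nendheader\n"
                    "time\tx\n0.0\t1.0\n0.1\n")
    with pytest.raises(ValueError, match="line 8"):
        read_sto(path)


def test_sto_rejects_nonmonotonic_time(tmp_path):
    with pytest.raises(ValueError, match="increasing"):
        write_sto(tmp_path / "t.sto", [0.0, 0.0, 0.1], {"x": [1, 2, 3]})
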