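import numpy as np
import pytest

from runopt3d import (ModelDefinition, SegmentSpec, JointSpec,
                      build_reduced_runner, synth_reference, cycles_to_reference)


@pytest.fixture(scope="session")
def runner():
    """The built-in reduced 3D runner (study subject anthropometry)."""
    return build_reduced_runner(92.0, 1.95)


@pytest.fixture(scope="session")
def pendulum():
    """Uniform rod pendulum, pin at the end: closed-form dynamics oracle."""
    L, mass = 1.0, 1.0
    I = mass * L * L / 12.0
    return ModelDefinition(
        segments=[SegmentSpec("rod", mass, ((I, 0, 0), (0, 1e-9, 0), (0, 0, I)),
                              (0.0, -L / 2.0, 0.0))],
        joints=[JointSpec("pin", "ground", "rod", "revolute1", axis=(0, 0, 1),
                          dof_names=("theta",), dof_bounds=((-10, 10),))],
        muscles=[], torque_actuators=[], subject_mass=mass, subject_height=1.0,
        grf_groups={})


@pytest.fixture(scope="session")
def reference(runner):
    """Synthetic straight-running reference at the study speed, 12 cycles."""
    return cycles_to_reference(synth_reference(runner, speed=4.0, n_cycles=12, seed=1), 24)


@pytest.fixture(scope="session")
def rand_state():
    return random_state


def random_state(model, rng, upright=True):
    """A random-but-sane full state/control pair within bounds."""
    lay = model.layout
    xb = model.state_bounds()
    x = xb[:, 0] + (xb[:, 1] - xb[:, 0]) * rng.uniform(0.25, 0.75, lay.n_x)
    if upright:
        x[model.dof_index["pelvis_ty"]] = 1.0
    ub = model.control_bounds()
    u = ub[:, 0] + (ub[:, 1] - ub[:, 0]) * rng.uniform(0.1, 0.9, lay.n_u)
    xd = rng.normal(0.0, 0.5, lay.n_x)
    return x, xd, u
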