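"""Shared fixtures: models are built once per session (symbolic cost)."""

import numpy as np
import pytest

import myospace as ms


@pytest.fixture(scope="session")
def arm():
    """The bundled 3-joint, 9-muscle arm at its experiment posture."""
    return ms.build_planar_arm(ms.default_arm_parameters(),
                               reference_posture=ms.default_initial_posture())


@pytest.fixture(scope="session")
def pendulum():
    """1-joint, 2-antagonist-muscle pendulum (no gravity)."""
    return ms.build_planar_arm(ms.pendulum_parameters())


@pytest.fixture(scope="session")
def pendulum_gravity():
    """Same pendulum under gravity (for statics/energy checks)."""
    return ms.build_planar_arm(ms.pendulum_parameters(gravity=(0.0, -9.81)))


@pytest.fixture(scope="session")
def linear_muscles(arm):
    return ms.MuscleModelSpec.linear(arm.f_max)


def random_state(model, rng, q_scale=0.4, qd_scale=0.5):
    """Random admissible state around the reference posture."""
    q = model.reference_posture + rng.uniform(-q_scale, q_scale,
                                              model.n_joints)
    qd = rng.uniform(-qd_scale, qd_scale, model.n_joints)
    return ms.ModelState(q=q, qdot=qd)
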