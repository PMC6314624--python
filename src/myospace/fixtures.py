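"""Deterministic random fixtures: models, polytopes and the 1-DoF toy.

Every fixture flows from a single named seed through one
``numpy.random.Generator``; there is no hidden global state, so the same
seed always reproduces the same object.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidInputError
from .model import ModelParameters, MusclePath, default_arm_parameters
from .polytope import Halfspaces

__all__ = ["generate_fixture", "random_model_parameters", "random_polytope",
           "toy_1dof", "pendulum_parameters"]


def random_model_parameters(seed: int) -> ModelParameters:
    """A random valid 3-joint, 9-muscle arm (perturbed default geometry).

    Segment lengths, masses, inertias and attachment offsets are scaled
    by moderate random factors; the construction keeps antagonist pairs
    on opposite sides of each joint, so the moment-arm matrix stays full
    rank at the reference posture.
    """
    rng = np.random.default_rng(seed)
    base = default_arm_parameters()
    L = tuple(v * rng.uniform(0.85, 1.15) for v in base.segment_lengths)
    Lc = tuple(li * rng.uniform(0.35, 0.55) for li in L)
    m = tuple(v * rng.uniform(0.7, 1.3) for v in base.masses)
    inertia = tuple(mi * li**2 * rng.uniform(1 / 14, 1 / 10)
                    for mi, li in zip(m, L))
    scale_h = rng.uniform(0.8, 1.3)
    scale_d = rng.uniform(0.9, 1.2)
    muscles = []
    for mus in base.muscles:
        pts = tuple((seg, (x * scale_d if abs(x) > 1e-9 else x,
                           y * scale_h)) for seg, (x, y) in mus.points)
        muscles.append(MusclePath(name=mus.name, points=pts))
    f_max = tuple(v * rng.uniform(0.8, 1.2) for v in base.f_max)
    params = ModelParameters(
        segment_lengths=L, com_distances=Lc, masses=m, inertias=inertia,
        muscles=tuple(muscles), f_max=f_max, gravity=base.gravity)
    params.validate()
    return params


def random_polytope(seed: int, r: int | None = None) -> Halfspaces:
    """A random bounded, feasible halfspace system ``Z y <= beta``.

    A box ``|y_i| <= c`` guarantees boundedness and containing the
    origin guarantees feasibility; a few random oblique cuts through the
    interior make the vertex structure non-trivial.
    """
    rng = np.random.default_rng(seed)
    if r is None:
        r = int(rng.integers(2, 5))
    c = rng.uniform(0.5, 2.0)
    Z = np.vstack([np.eye(r), -np.eye(r)])
    beta = np.full(2 * r, c)
    n_cuts = int(rng.integers(1, 5))
    for _ in range(n_cuts):
        a = rng.normal(size=r)
        a /= np.linalg.norm(a)
        b = rng.uniform(0.3, 1.0) * c
        Z = np.vstack([Z, a])
        beta = np.append(beta, b)
    return Halfspaces(Z=Z, beta=beta)


def pendulum_parameters(gravity=(0.0, 0.0)) -> ModelParameters:
    """A single pendulum (1 joint) actuated by two antagonist muscles."""
    L, Lc, m = 0.3, 0.15, 1.0
    d, h = 0.06, 0.025
    muscles = (
        MusclePath("flex", ((0, (-d, h)), (1, (d, h)))),
        MusclePath("ext", ((0, (-d, -h)), (1, (d, -h)))),
    )
    return ModelParameters(
        segment_lengths=(L,), com_distances=(Lc,), masses=(m,),
        inertias=(m * L**2 / 12,), muscles=muscles,
        f_max=(200.0, 200.0), gravity=tuple(gravity))


def toy_1dof() -> dict:
    """The 1-DoF, 2-muscle worked example.

    Returns the matrix-level toy (``R = [[1], [1]]``, unit force bounds)
    used throughout the worked examples, together with pendulum model
    parameters for a geometric realization of a 1-joint antagonist pair.
    """
    return {
        "R": np.array([[1.0], [1.0]]),
        "f_max": np.array([1.0, 1.0]),
        "params": pendulum_parameters(),
    }


def generate_fixture(kind: str, seed: int = 0):
    """Dispatch fixture generation by kind; deterministic per seed."""
    if kind == "random_model":
        return random_model_parameters(seed)
    if kind == "random_polytope":
        return random_polytope(seed)
    if kind == "toy_1dof":
        return toy_1dof()
    raise InvalidInputError(
        f"unknown fixture kind {kind!r}; expected random_model, "
        "random_polytope or toy_1dof")
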