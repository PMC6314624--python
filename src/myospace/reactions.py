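"""Joint reaction (constraint) forces under redundant muscle loading.

The net joint torque fixes the movement but not the reaction loads: any
null-space muscle co-contraction presses the articular surfaces together
without moving the limb.  Reactions are computed by a planar
Newton-Euler recursion over the linkage with each muscle applied as a
pair of equal-and-opposite path forces at its attachment points (tension
pulls each attachment toward its neighbour along the path).  Sweeping the
feasible muscle-force set yields per-joint reaction envelopes; because
the reaction is affine in the muscle forces, its component-wise extremes
over the polytope are attained at the sampled vertices, so the envelope
brackets the reaction of any interior solution (in particular the
minimum-null-norm one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError
from .model import PlanarArm
from .polytope import FeasibleForceSet, min_norm_point

__all__ = ["joint_reaction_forces", "ReactionEnvelope", "joint_reaction_bounds"]


def _muscle_forces_on_segments(model: PlanarArm, q, fm):
    """Resultant muscle force on each segment (n, 2) from path tensions."""
    points, hosts = model.muscle_path_points(q)
    n = model.n_joints
    out = np.zeros((n, 2))
    for i, (pts, segs) in enumerate(zip(points, hosts)):
        tension = fm[i]
        if tension == 0.0:
            continue
        for j, seg in enumerate(segs):
            if seg == 0:
                continue  # forces on ground do not load the chain
            pull = np.zeros(2)
            for k in (j - 1, j + 1):
                if 0 <= k < len(pts):
                    d = pts[k] - pts[j]
                    norm = np.linalg.norm(d)
                    if norm > 1e-12:
                        pull += d / norm
            out[seg - 1] += tension * pull
    return out


def joint_reaction_forces(model: PlanarArm, q, qd, qdd, fm,
                          external_force=None) -> np.ndarray:
    """Reaction force transmitted from segment ``k-1`` to segment ``k``
    at joint ``k``, for all joints; shape (n, 2) [N].

    Newton's law per segment: the joint reactions balance inertial,
    gravitational, muscular and external forces.  ``external_force`` (2,)
    is applied at the chain tip.
    """
    q = np.asarray(q, float).reshape(-1)
    qd = np.asarray(qd, float).reshape(-1)
    qdd = np.asarray(qdd, float).reshape(-1)
    fm = np.asarray(fm, float).reshape(-1)
    n = model.n_joints
    if qdd.shape[0] != n:
        raise InvalidInputError("joint_reaction_forces needs qdd of length n")
    if fm.shape[0] != model.n_muscles:
        raise InvalidInputError("fm dimension mismatch")
    acc = model.com_accelerations(q, qd, qdd)
    fmus = _muscle_forces_on_segments(model, q, fm)
    g = np.asarray(model.params.gravity, float)
    masses = np.asarray(model.params.masses, float)
    F = np.zeros((n, 2))
    F_child = np.zeros(2)  # force exerted by segment k on segment k+1
    for k in range(n - 1, -1, -1):
        fext = np.zeros(2)
        if k == n - 1 and external_force is not None:
            fext = np.asarray(external_force, float).reshape(2)
        F[k] = masses[k] * (acc[k] - g) - fmus[k] - fext + F_child
        F_child = F[k]
    return F


@dataclass(frozen=True)
class ReactionEnvelope:
    """Per-joint reaction-force envelopes over a feasible force set.

    ``lo``/``hi`` are component-wise bounds (T, n, 2); ``mag_lo``/
    ``mag_hi`` bound the reaction magnitude over the samples (T, n); the
    ``min_norm`` trajectory (T, n, 2) is the reaction of the
    minimum-null-norm muscle solution at each time.
    """

    times: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    mag_lo: np.ndarray
    mag_hi: np.ndarray
    min_norm: np.ndarray

    def contains(self, reactions: np.ndarray, tol: float = 1e-8) -> bool:
        """Component-wise membership of a (T, n, 2) reaction trajectory."""
        return bool(np.all(reactions >= self.lo - tol)
                    and np.all(reactions <= self.hi + tol))


def joint_reaction_bounds(model: PlanarArm, trajectory,
                          fsets) -> ReactionEnvelope:
    """Reaction envelopes over a movement for per-time feasible force sets.

    ``trajectory`` is a sequence of ``(t, q, qd, qdd)``; ``fsets`` the
    matching :class:`FeasibleForceSet` per time step (consistent
    kinematics, i.e. ``qdd`` must be supplied).
    """
    trajectory = list(trajectory)
    fsets = list(fsets)
    if len(trajectory) != len(fsets):
        raise InvalidInputError("trajectory and fsets lengths differ")
    n = model.n_joints
    T = len(trajectory)
    lo = np.full((T, n, 2), np.inf)
    hi = np.full((T, n, 2), -np.inf)
    mag_lo = np.full((T, n), np.inf)
    mag_hi = np.full((T, n), -np.inf)
    mn = np.zeros((T, n, 2))
    times = np.zeros(T)
    for s, ((t, q, qd, qdd), fset) in enumerate(zip(trajectory, fsets)):
        if qdd is None:
            raise InvalidInputError("trajectory step is missing qdd")
        times[s] = t
        for fm in fset.samples:
            F = joint_reaction_forces(model, q, qd, qdd, fm)
            lo[s] = np.minimum(lo[s], F)
            hi[s] = np.maximum(hi[s], F)
            mag = np.linalg.norm(F, axis=1)
            mag_lo[s] = np.minimum(mag_lo[s], mag)
            mag_hi[s] = np.maximum(mag_hi[s], mag)
        y_star = min_norm_point(fset.halfspaces)
        fm_star = fset.fm_par + fset.halfspaces.basis @ y_star
        mn[s] = joint_reaction_forces(model, q, qd, qdd, fm_star)
    return ReactionEnvelope(times=times, lo=lo, hi=hi,
                            mag_lo=mag_lo, mag_hi=mag_hi, min_norm=mn)
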