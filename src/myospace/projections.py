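"""Task- and muscle-space projections of the joint-space equations of motion.

Joint-space dynamics ``M qdd + f = tau`` are mapped onto

* task space: ``Lambda_t (xtdd + b_t) + Jbar_t' f = ft`` with the task
  inertia ``Lambda_t = (Jt M^-1 Jt')^-1``, bias ``b_t = -Jtdot qd`` and
  the dynamically consistent inverse ``Jbar_t' = Lambda_t Jt M^-1`` —
  the unique generalized inverse for which joint torques in the task
  null space produce zero task acceleration;

* muscle space: ``-Lambda_m (lmdd + b_m) - R+' f = fm_par + N_TR fm0``
  with ``Lambda_m = (R M^-1 R')+``, bias ``b_m = -Rdot qd - Ndot_TR
  lmdot0`` and the moment-arm null projector ``N_TR = I - R R+``; the
  null term ``N_TR fm0`` changes muscle co-contraction without changing
  joint torque or movement.

Force maps between the spaces (``tau = Jt' ft + N_FJt tau0``,
``fm = -R+' tau + N_TR fm0``) and the three equivalent routes to a
particular muscle-force solution are provided alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (InvalidInputError, KinematicSingularityError,
                         RankDeficiencyError)
from .linalg import DEFAULT_RTOL, projectors
from .model import (ModelState, PlanarArm, evaluate_dynamics,
                    evaluate_muscle_kinematics, evaluate_task_kinematics)

__all__ = [
    "TaskProjection", "MuscleProjection", "task_projection",
    "muscle_projection", "task_force_map", "muscle_force_map",
    "particular_muscle_forces",
]


@dataclass(frozen=True)
class TaskProjection:
    """Task-space dynamic quantities at one state."""

    Lambda_t: np.ndarray   # task-space inertia (d x d)
    b_t: np.ndarray        # task bias = -Jtdot qd (d,)
    Jbar_T: np.ndarray     # dynamically consistent inverse transpose (d x n)
    N_FJt: np.ndarray      # MPP task null-space projector I - Jt+ Jt (n x n)
    Theta: np.ndarray      # coupled task-muscle map Jt R+ (d x m)
    Jt: np.ndarray
    Jt_pinv: np.ndarray
    M: np.ndarray
    f: np.ndarray


@dataclass(frozen=True)
class MuscleProjection:
    """Muscle-space dynamic quantities at one state."""

    Lambda_m: np.ndarray   # muscle-space inertia (m x m)
    b_m: np.ndarray        # muscle bias = -Rdot qd - Ndot_TR lmdot0 (m,)
    N_TR: np.ndarray       # moment-arm null projector I - R R+ (m x m)
    RplusT: np.ndarray     # projection map R+' (m x n)
    Ndot_TR: np.ndarray    # time derivative of N_TR (m x m)
    lmdot0: np.ndarray     # free null-space muscle velocity (m,)
    R: np.ndarray
    R_pinv: np.ndarray
    lm: np.ndarray
    Rdot: np.ndarray
    M: np.ndarray
    f: np.ndarray


def task_projection(model: PlanarArm, state: ModelState,
                    external_torque=None,
                    rtol: float = DEFAULT_RTOL) -> TaskProjection:
    """Project the equations of motion onto the end-effector task space.

    Requires the task Jacobian to have full row rank at the state; a
    kinematic singularity raises rather than being damped or regularized.
    """
    dyn = evaluate_dynamics(model, state, external_torque)
    kin = evaluate_task_kinematics(model, state)
    Jt = kin.Jt
    d = Jt.shape[0]
    Minv = np.linalg.inv(dyn.M)
    A = Jt @ Minv @ Jt.T
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1.0 / rtol:
        raise KinematicSingularityError(
            f"task-space inertia is singular (cond={cond:.2e}) — "
            "the arm is at a kinematic singularity")
    Lambda_t = np.linalg.inv(A)
    Lambda_t = 0.5 * (Lambda_t + Lambda_t.T)
    bundle = projectors(Jt, rtol=rtol)
    return TaskProjection(
        Lambda_t=Lambda_t,
        b_t=-(kin.Jtdot @ state.qdot),
        Jbar_T=Lambda_t @ Jt @ Minv,
        N_FJt=bundle.N_F,
        Theta=Jt @ _moment_arm_pinv(model, state, rtol),
        Jt=Jt,
        Jt_pinv=bundle.pinv,
        M=dyn.M,
        f=dyn.f,
    )


def _moment_arm_pinv(model, state, rtol):
    R = model.moment_arm(state.q)
    return projectors(R, rtol=rtol).pinv


def _ntr_dot(model, state, rtol, dt: float = 1e-5) -> np.ndarray:
    """Time derivative of N_TR by central differences along the trajectory.

    The projector is differentiated at fixed rank by evaluating it at
    ``q +/- qd * dt``; the analytic form ``-(Rdot R+ + R d(R+)/dt)`` is
    avoided because d(R+)/dt is awkward to state robustly.
    """
    qp = state.q + state.qdot * dt
    qm = state.q - state.qdot * dt
    Np = projectors(model.moment_arm(qp), rtol=rtol).N_T
    Nm = projectors(model.moment_arm(qm), rtol=rtol).N_T
    return (Np - Nm) / (2.0 * dt)


def muscle_projection(model: PlanarArm, state: ModelState,
                      lmdot0=None, external_torque=None,
                      rtol: float = DEFAULT_RTOL) -> MuscleProjection:
    """Project the equations of motion onto muscle space.

    ``Lambda_m`` uses the pseudoinverse, since ``R M^-1 R'`` has rank
    ``n < m`` by construction.  ``lmdot0`` is the free null-space muscle
    velocity (default zero, the unbiased strategy).
    """
    dyn = evaluate_dynamics(model, state, external_torque)
    kin = evaluate_muscle_kinematics(model, state)
    R = kin.R
    m, n = R.shape
    bundle = projectors(R, rtol=rtol)
    if bundle.rank < n:
        raise RankDeficiencyError(
            f"moment-arm matrix rank {bundle.rank} < {n} at this state")
    if lmdot0 is None:
        lmdot0 = np.zeros(m)
    lmdot0 = np.asarray(lmdot0, dtype=float).reshape(-1)
    if lmdot0.shape[0] != m:
        raise InvalidInputError("lmdot0 dimension mismatch")
    Minv = np.linalg.inv(dyn.M)
    Lambda_m = projectors(R @ Minv @ R.T, rtol=rtol).pinv
    Lambda_m = 0.5 * (Lambda_m + Lambda_m.T)
    N_TR = bundle.N_T
    if np.any(lmdot0 != 0.0) or np.any(state.qdot != 0.0):
        Ndot_TR = _ntr_dot(model, state, rtol)
    else:
        Ndot_TR = np.zeros((m, m))
    b_m = -(kin.Rdot @ state.qdot) - Ndot_TR @ lmdot0
    return MuscleProjection(
        Lambda_m=Lambda_m,
        b_m=b_m,
        N_TR=N_TR,
        RplusT=bundle.pinv.T,
        Ndot_TR=Ndot_TR,
        lmdot0=lmdot0,
        R=R,
        R_pinv=bundle.pinv,
        lm=kin.lm,
        Rdot=kin.Rdot,
        M=dyn.M,
        f=dyn.f,
    )


def task_force_map(ft: np.ndarray, tau0: np.ndarray,
                   proj: TaskProjection) -> np.ndarray:
    """Joint torques realizing a task force plus a null-space torque:
    ``tau = Jt' ft + N_FJt tau0``.  The inverse map ``ft = Jt+' tau``
    recovers ``ft`` exactly when ``tau0 = 0``."""
    ft = np.asarray(ft, dtype=float).reshape(-1)
    tau0 = np.asarray(tau0, dtype=float).reshape(-1)
    d, n = proj.Jt.shape
    if ft.shape[0] != d or tau0.shape[0] != n:
        raise InvalidInputError("task_force_map dimension mismatch")
    return proj.Jt.T @ ft + proj.N_FJt @ tau0


def muscle_force_map(tau: np.ndarray, fm0: np.ndarray,
                     proj: MuscleProjection) -> np.ndarray:
    """Muscle forces realizing a joint torque plus a null-space term:
    ``fm = -R+' tau + N_TR fm0``; the sign convention makes shortening
    muscles do positive work (``tau = -R' fm``)."""
    tau = np.asarray(tau, dtype=float).reshape(-1)
    fm0 = np.asarray(fm0, dtype=float).reshape(-1)
    m, n = proj.R.shape
    if tau.shape[0] != n or fm0.shape[0] != m:
        raise InvalidInputError("muscle_force_map dimension mismatch")
    return -proj.RplusT @ tau + proj.N_TR @ fm0


def particular_muscle_forces(model: PlanarArm, state: ModelState,
                             route: str, motion: np.ndarray,
                             external_torque=None,
                             lmdot0=None,
                             rtol: float = DEFAULT_RTOL) -> np.ndarray:
    """Particular muscle-force solution realizing a desired motion.

    Three equivalent routes, differing in which space the motion goal is
    expressed:

    * ``route="task"``:   motion = task acceleration ``xtdd`` (d,);
      ``fm_par = -Theta' (Lambda_t (xtdd + b_t) + Jbar_t' f)``
    * ``route="joint"``:  motion = joint acceleration ``qdd`` (n,);
      ``fm_par = -R+' (M qdd + f)``
    * ``route="muscle"``: motion = muscle length acceleration ``lmdd`` (m,);
      ``fm_par = -Lambda_m (lmdd + b_m) - R+' f``

    The routes agree whenever the torque realizing the motion has no
    component in the task null space (joint and muscle routes always
    agree for kinematically consistent goals).
    """
    motion = np.asarray(motion, dtype=float).reshape(-1)
    if route == "joint":
        if motion.shape[0] != model.n_joints:
            raise InvalidInputError("joint route expects qdd of length n")
        dyn = evaluate_dynamics(model, state, external_torque)
        RplusT = _moment_arm_pinv(model, state, rtol).T
        return -RplusT @ (dyn.M @ motion + dyn.f)
    if route == "task":
        tp = task_projection(model, state, external_torque, rtol=rtol)
        if motion.shape[0] != tp.Jt.shape[0]:
            raise InvalidInputError("task route expects xtdd of length d")
        ft = tp.Lambda_t @ (motion + tp.b_t) + tp.Jbar_T @ tp.f
        return -tp.Theta.T @ ft
    if route == "muscle":
        mp = muscle_projection(model, state, lmdot0, external_torque, rtol=rtol)
        if motion.shape[0] != model.n_muscles:
            raise InvalidInputError("muscle route expects lmdd of length m")
        return -mp.Lambda_m @ (motion + mp.b_m) - mp.RplusT @ mp.f
    raise InvalidInputError(f"unknown route {route!r}; "
                            "expected 'task', 'joint' or 'muscle'")
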