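"""Reflex and task-space controllers in a mixed-dynamics simulation.

Mixed dynamics couples an inverse-dynamics model-based controller to a
forward-dynamics plant: at every step the controller turns a goal
(muscle-length acceleration for the spinal reflex scheme, task
acceleration for reaching) into muscle forces through the corresponding
space projection, and the plant integrates ``M qdd + f = -R' fm``
forward.  Sensory feedback to the reflex loop is delayed by the spindle
conduction time ``tau_so`` via a dense state-history buffer with linear
interpolation.  Muscle forces always pass through the feasibility
correction (minimum-norm null-space term subject to the force bounds),
so every applied force is physiological.  Integration is fixed-step
RK4 with the controller held over each step — fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import CapacityError, InvalidInputError, SimulationDivergedError
from .model import ModelState, PlanarArm
from .polytope import (MuscleModelSpec, build_force_inequalities,
                       min_norm_point)
from .projections import muscle_projection, task_projection

__all__ = [
    "ReflexParams", "DisturbanceSpec", "TrajectorySpec", "SimulationResult",
    "reflex_muscle_goal", "gaussian_disturbance", "sigmoid_task_trajectory",
    "muscle_space_controller", "task_space_controller",
    "ReflexController", "TaskController", "DelayBuffer", "simulate",
    "default_initial_posture", "max_vertex_strategy",
]


# ---------------------------------------------------------------------------
# parameter specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReflexParams:
    """Spinal-reflex posture controller parameters.

    ``kp`` [1/s^2] and ``kd`` [1/s] are the length / velocity reflex
    gains, ``tau_so`` [s] the spindle conduction delay, ``lmd`` [m] the
    desired (initial) muscle lengths.
    """

    kp: float = 10.0
    kd: float = 10.0
    tau_so: float = 0.02
    lmd: np.ndarray | None = None

    def __post_init__(self):
        if self.kp < 0 or self.kd < 0 or self.tau_so < 0:
            raise InvalidInputError("reflex gains and delay must be >= 0")


@dataclass(frozen=True)
class DisturbanceSpec:
    """Gaussian force impulse applied at the end effector.

    ``f(t) = a exp(-(t - t0)^2 / sigma^2) * direction`` with magnitude
    ``a`` [N], application time ``t0`` [s] and width ``sigma`` [s].
    Defaults follow the posture experiment: 15 N at 0.1 s, width 0.01 s,
    acting along -x.
    """

    a: float = 15.0
    t0: float = 0.1
    sigma: float = 0.01
    direction: tuple = (-1.0, 0.0)

    def __post_init__(self):
        if self.sigma <= 0:
            raise InvalidInputError("sigma must be > 0")
        d = np.asarray(self.direction, float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-8:
            raise InvalidInputError("direction must be a unit vector")


@dataclass(frozen=True)
class TrajectorySpec:
    """Smooth point-to-point task trajectory with bell-shaped speed.

    Displacement ``a/2 (tanh(b (t - t0)) + 1)`` [m] along +x rotated by
    ``gamma`` about z; ``b`` [1/s] sets the steepness (peak speed
    ``a b / 2`` at ``t0``).  Defaults follow the reaching experiment:
    a = 0.3 m, b = 4 /s, t0 = 1 s.
    """

    a: float = 0.3
    b: float = 4.0
    t0: float = 1.0
    gamma: float = 0.0


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def reflex_muscle_goal(lm_delayed, lmdot_delayed,
                       params: ReflexParams) -> np.ndarray:
    """Muscle length acceleration goal of the stretch-reflex law:
    ``lmdd = kp (lmd - lm(t - tau)) - kd lmdot(t - tau)``."""
    lm_delayed = np.asarray(lm_delayed, float).reshape(-1)
    lmdot_delayed = np.asarray(lmdot_delayed, float).reshape(-1)
    if params.lmd is None:
        raise InvalidInputError("ReflexParams.lmd is not set")
    lmd = np.asarray(params.lmd, float).reshape(-1)
    return params.kp * (lmd - lm_delayed) - params.kd * lmdot_delayed


def gaussian_disturbance(t: float, spec: DisturbanceSpec) -> np.ndarray:
    """Task-space force [N] of the Gaussian impulse at time ``t``."""
    mag = spec.a * np.exp(-((t - spec.t0) ** 2) / spec.sigma**2)
    return mag * np.asarray(spec.direction, float)


def sigmoid_task_trajectory(t: float, xt0, spec: TrajectorySpec):
    """Desired task position, velocity and acceleration at time ``t``.

    The base profile displaces along +x from the start position ``xt0``;
    the goal is rotated by ``H_z(gamma)`` about the start position.
    """
    xt0 = np.asarray(xt0, float).reshape(2)
    u = spec.b * (t - spec.t0)
    th = np.tanh(u)
    sech2 = 1.0 - th**2
    s = 0.5 * spec.a * (th + 1.0)
    sd = 0.5 * spec.a * spec.b * sech2
    sdd = -spec.a * spec.b**2 * sech2 * th
    c, g = np.cos(spec.gamma), np.sin(spec.gamma)
    Hz = np.array([[c, -g], [g, c]])
    e = Hz @ np.array([1.0, 0.0])
    return xt0 + s * e, sd * e, sdd * e


def max_vertex_strategy(H):
    """Pick the feasible null-space correction of maximal norm (a polytope
    vertex) instead of the minimal one — maximal co-contraction.  Used to
    demonstrate that the null-space choice is invisible in the movement."""
    from .polytope import enumerate_vertices

    vs = enumerate_vertices(H)
    if len(vs.vertices) == 0:
        raise CapacityError("empty feasible polytope")
    norms = np.linalg.norm(vs.vertices, axis=1)
    return vs.vertices[int(np.argmax(norms))]


def muscle_space_controller(model: PlanarArm, state: ModelState,
                            lmddot_goal, muscle_model: MuscleModelSpec,
                            lmdot0=None, external_torque=None,
                            null_strategy=None):
    """Muscle forces realizing a muscle-length acceleration goal.

    Solves the muscle-space equations of motion for the particular force
    ``fm_par = -Lambda_m (lmdd + b_m) - R+' f`` (ignoring the null
    term), then finds the minimum-norm null-space correction ``fm0``
    keeping the total force inside the muscle-model bounds (a quadratic
    program over the feasible polytope), and returns
    ``fm = fm_par + N_TR fm0``.
    """
    mp = muscle_projection(model, state, lmdot0=lmdot0,
                           external_torque=external_torque)
    goal = np.asarray(lmddot_goal, float).reshape(-1)
    if goal.shape[0] != model.n_muscles:
        raise InvalidInputError("lmddot_goal must have length m")
    fm_par = -mp.Lambda_m @ (goal + mp.b_m) - mp.RplusT @ mp.f
    H = build_force_inequalities(fm_par, muscle_model, mp.N_TR,
                                 lm=mp.lm, lmdot=mp.R @ state.qdot)
    try:
        y = (null_strategy or min_norm_point)(H)
    except Exception as err:
        raise CapacityError(
            "goal exceeds muscle capacity: no feasible null-space "
            "correction exists") from err
    return fm_par + H.basis @ y


def task_space_controller(model: PlanarArm, state: ModelState,
                          xd, xd_dot, xd_ddot,
                          kp: float = 50.0, kd: float = 5.0):
    """Task force and joint torque tracking a desired task trajectory.

    PD-corrected command ``xdd_cmd = xdd_d + kp (xd - xt) + kd (xd_dot -
    xt_dot)`` mapped through the task-space equations of motion
    (``ft = Lambda_t (xdd_cmd + b_t) + Jbar_t' f``, ``tau = Jt' ft``,
    no secondary null-space objective).
    """
    tp = task_projection(model, state)
    xt = model.task_position(state.q)
    xt_dot = tp.Jt @ state.qdot
    cmd = (np.asarray(xd_ddot, float) + kp * (np.asarray(xd, float) - xt)
           + kd * (np.asarray(xd_dot, float) - xt_dot))
    ft = tp.Lambda_t @ (cmd + tp.b_t) + tp.Jbar_T @ tp.f
    tau = tp.Jt.T @ ft
    return ft, tau


# ---------------------------------------------------------------------------
# controllers and simulation loop
# ---------------------------------------------------------------------------

class DelayBuffer:
    """Dense history of muscle states for delayed sensory feedback.

    Records ``(t, lm, lmdot)`` every step; lookups linearly interpolate
    and clamp to the initial state for times before the history starts.
    """

    def __init__(self):
        self._t: list[float] = []
        self._lm: list[np.ndarray] = []
        self._lmdot: list[np.ndarray] = []

    def append(self, t: float, lm: np.ndarray, lmdot: np.ndarray) -> None:
        self._t.append(float(t))
        self._lm.append(np.asarray(lm, float).copy())
        self._lmdot.append(np.asarray(lmdot, float).copy())

    def lookup(self, t: float):
        if not self._t:
            raise InvalidInputError("empty delay buffer")
        ts = self._t
        if t <= ts[0]:
            return self._lm[0], self._lmdot[0]
        if t >= ts[-1]:
            return self._lm[-1], self._lmdot[-1]
        i = int(np.searchsorted(ts, t, side="right")) - 1
        w = (t - ts[i]) / (ts[i + 1] - ts[i])
        lm = (1 - w) * self._lm[i] + w * self._lm[i + 1]
        lmdot = (1 - w) * self._lmdot[i] + w * self._lmdot[i + 1]
        return lm, lmdot


class ReflexController:
    """Spinal posture controller: delayed length feedback -> muscle forces.

    ``null_strategy`` selects the feasible null-space correction (default:
    minimum norm); any choice yields the same movement.
    """

    def __init__(self, params: ReflexParams, muscle_model: MuscleModelSpec,
                 null_strategy=None):
        self.params = params
        self.muscle_model = muscle_model
        self.null_strategy = null_strategy

    def start(self, model: PlanarArm, state: ModelState):
        if self.params.lmd is None:
            lmd = model.muscle_lengths(state.q)
            self.params = ReflexParams(kp=self.params.kp, kd=self.params.kd,
                                       tau_so=self.params.tau_so, lmd=lmd)

    def __call__(self, model, t, state, history: DelayBuffer):
        lm_d, lmdot_d = history.lookup(t - self.params.tau_so)
        goal = reflex_muscle_goal(lm_d, lmdot_d, self.params)
        fm = muscle_space_controller(model, state, goal, self.muscle_model,
                                     null_strategy=self.null_strategy)
        return fm, {}


class TaskController:
    """Reaching controller: task-space tracking mapped to muscle forces."""

    def __init__(self, spec: TrajectorySpec, muscle_model: MuscleModelSpec,
                 kp: float = 50.0, kd: float = 5.0):
        self.spec = spec
        self.muscle_model = muscle_model
        self.kp = kp
        self.kd = kd
        self.xt0 = None

    def start(self, model: PlanarArm, state: ModelState):
        self.xt0 = model.task_position(state.q)

    def desired(self, t: float):
        return sigmoid_task_trajectory(t, self.xt0, self.spec)

    def __call__(self, model, t, state, history):
        xd, xd_dot, xd_ddot = self.desired(t)
        ft, tau = task_space_controller(model, state, xd, xd_dot, xd_ddot,
                                        kp=self.kp, kd=self.kd)
        mp = muscle_projection(model, state)
        fm_par = -mp.RplusT @ tau
        H = build_force_inequalities(fm_par, self.muscle_model, mp.N_TR,
                                     lm=mp.lm, lmdot=mp.R @ state.qdot)
        try:
            y = min_norm_point(H)
        except Exception as err:
            raise CapacityError("commanded task force exceeds muscle "
                                "capacity") from err
        fm = fm_par + H.basis @ y
        return fm, {"ft": ft, "xd": xd}


@dataclass
class SimulationResult:
    """Aligned time series of one mixed-dynamics simulation."""

    time: np.ndarray                 # (T,) [s]
    q: np.ndarray                    # (T, n) [rad]
    qdot: np.ndarray                 # (T, n) [rad/s]
    lm: np.ndarray                   # (T, m) [m]
    lmdot: np.ndarray                # (T, m) [m/s]
    fm: np.ndarray | None            # (T, m) [N] or None (unactuated run)
    xt: np.ndarray                   # (T, d) [m]
    ft: np.ndarray | None            # (T, d) [N], task experiments only
    muscle_names: tuple = ()
    parameters: dict = field(default_factory=dict)


def simulate(model: PlanarArm, controller, duration: float,
             dt: float = 1e-3, disturbance: DisturbanceSpec | None = None,
             initial_state: ModelState | None = None) -> SimulationResult:
    """Integrate the forward-dynamics plant under a muscle controller.

    The controller (or ``None`` for a passive plant) is evaluated once
    per step on the true state plus delayed feedback from the history
    buffer; the returned muscle force is held over the RK4 step while
    the moment arms and the disturbance are re-evaluated at every stage.
    Aborts if joint velocities explode.
    """
    if dt <= 0:
        raise InvalidInputError("dt must be > 0")
    n = model.n_joints
    if initial_state is None:
        initial_state = ModelState(q=model.reference_posture.copy(),
                                   qdot=np.zeros(n))
    q = initial_state.q.copy()
    qd = initial_state.qdot.copy()
    steps = int(round(duration / dt))
    history = DelayBuffer()
    if controller is not None and hasattr(controller, "start"):
        controller.start(model, ModelState(q=q, qdot=qd, time=0.0))

    def accel(t, q_, qd_, tau_m):
        # the muscle torque -R' fm is held over the step (zero-order hold
        # at the actuation level), so null-space forces stay exactly
        # movement-invisible; the disturbance is re-evaluated per stage
        M = model.mass_matrix(q_, qd_)
        bias = model.bias_force(q_, qd_)
        tau = tau_m.copy()
        if disturbance is not None:
            fd = gaussian_disturbance(t, disturbance)
            tau = tau + model.task_jacobian(q_, qd_).T @ fd
        return np.linalg.solve(M, tau - bias)

    T = steps + 1
    m = model.n_muscles
    rec = {
        "time": np.zeros(T), "q": np.zeros((T, n)), "qdot": np.zeros((T, n)),
        "lm": np.zeros((T, m)), "lmdot": np.zeros((T, m)),
        "fm": np.zeros((T, m)), "xt": np.zeros((T, 2)),
        "ft": np.full((T, 2), np.nan),
    }
    have_fm = controller is not None
    have_ft = False
    for k in range(T):
        t = k * dt
        R = model.moment_arm(q, qd)
        lm = model.muscle_lengths(q, qd)
        lmdot = R @ qd
        history.append(t, lm, lmdot)
        state = ModelState(q=q, qdot=qd, time=t)
        fm, extras = (None, {})
        if controller is not None:
            fm, extras = controller(model, t, state, history)
        rec["time"][k] = t
        rec["q"][k] = q
        rec["qdot"][k] = qd
        rec["lm"][k] = lm
        rec["lmdot"][k] = lmdot
        rec["xt"][k] = model.task_position(q, qd)
        if fm is not None:
            rec["fm"][k] = fm
        if "ft" in extras:
            rec["ft"][k] = extras["ft"]
            have_ft = True
        if k == steps:
            break
        tau_m = -R.T @ fm if fm is not None else np.zeros(n)
        k1q, k1v = qd, accel(t, q, qd, tau_m)
        k2q = qd + 0.5 * dt * k1v
        k2v = accel(t + 0.5 * dt, q + 0.5 * dt * k1q, k2q, tau_m)
        k3q = qd + 0.5 * dt * k2v
        k3v = accel(t + 0.5 * dt, q + 0.5 * dt * k2q, k3q, tau_m)
        k4q = qd + dt * k3v
        k4v = accel(t + dt, q + dt * k3q, k4q, tau_m)
        q = q + dt / 6.0 * (k1q + 2 * k2q + 2 * k3q + k4q)
        qd = qd + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        if not np.all(np.isfinite(qd)) or np.linalg.norm(qd) > 1e3:
            raise SimulationDivergedError(
                f"integration diverged at t = {t + dt:.4f} s "
                f"(||qdot|| = {np.linalg.norm(qd):.3e})")
    return SimulationResult(
        time=rec["time"], q=rec["q"], qdot=rec["qdot"],
        lm=rec["lm"], lmdot=rec["lmdot"],
        fm=rec["fm"] if have_fm else None,
        xt=rec["xt"], ft=rec["ft"] if have_ft else None,
        muscle_names=tuple(model.muscle_names),
        parameters={"duration": duration, "dt": dt},
    )


def default_initial_posture() -> np.ndarray:
    """Documented default initial posture for the bundled arm experiments.

    A mid-range elbow-flexed configuration placing the hand at roughly
    (0.30, 0.30) m, far from kinematic singularities and leaving all
    four cardinal reaching directions (0.3 m displacement) inside the
    workspace with the moment-arm matrix full rank throughout.
    """
    return np.array([-0.32734084, 1.5055769, 1.20899096])
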