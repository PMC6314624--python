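"""Analytic planar linkage models with polyline muscle paths.

The model is an ``n``-joint planar chain of rigid segments actuated by
``m > n`` muscles routed as straight-line (or via-point polyline) paths
between attachment points fixed in segment frames.  All quantities the
projection framework needs — joint-space inertia ``M(q)``, bias forces
``f(q, qd)``, musculotendon lengths ``lm(q)``, the moment-arm matrix
``R = d lm / d q`` and its time derivative, the end-effector task map
``g(q)`` with Jacobian ``Jt`` and ``Jt_dot`` — are derived symbolically
(Lagrangian dynamics + Euclidean path lengths) and compiled to fast
numeric callables, so higher-order derivatives are exact rather than
finite-differenced.

Conventions: relative revolute joint angles, counter-clockwise positive;
the zero posture is the chain fully extended along +x; the first joint
sits at the world origin; segment index 0 denotes the ground frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import sympy as sp

from .exceptions import ConfigurationError, GeometryError, InvalidInputError

__all__ = [
    "MusclePath", "ModelParameters", "ModelState", "DynamicsEval",
    "MuscleKinematicsEval", "TaskKinematicsEval", "PlanarArm",
    "build_planar_arm", "default_arm_parameters",
    "evaluate_dynamics", "evaluate_muscle_kinematics",
    "evaluate_task_kinematics",
]


@dataclass(frozen=True)
class MusclePath:
    """A muscle routed as a polyline through points fixed on segments.

    Each point is ``(segment_index, (x, y))`` in the host segment's frame;
    segment index 0 is the ground frame (world coordinates).  The first
    point is the origin, the last the insertion; intermediate entries are
    fixed via-points.
    """

    name: str
    points: tuple

    def __post_init__(self):
        if len(self.points) < 2:
            raise ConfigurationError(
                f"muscle {self.name!r}: needs at least origin and insertion")


@dataclass(frozen=True)
class ModelParameters:
    """Physical parameters of a planar linkage (SI units).

    segment_lengths ``L_i`` [m], com_distances ``Lc_i`` [m] (along the
    segment from its proximal joint), masses [kg], inertias [kg m^2]
    (about each segment's center of mass), gravity [m/s^2] as a planar
    vector (default zero), the muscle routing, and per-muscle maximum
    isometric forces ``f_max`` [N].
    """

    segment_lengths: tuple
    com_distances: tuple
    masses: tuple
    inertias: tuple
    muscles: tuple
    f_max: tuple
    gravity: tuple = (0.0, 0.0)
    joint_damping: tuple = ()   # passive viscous damping [N m s/rad], 0 if empty

    @property
    def n_joints(self) -> int:
        return len(self.segment_lengths)

    @property
    def n_muscles(self) -> int:
        return len(self.muscles)

    def validate(self) -> None:
        """Check all structural invariants; raise ConfigurationError naming
        the offending field."""
        n = self.n_joints
        for name in ("com_distances", "masses", "inertias"):
            if len(getattr(self, name)) != n:
                raise ConfigurationError(
                    f"{name}: expected {n} entries, got {len(getattr(self, name))}")
        for i, (L, Lc) in enumerate(zip(self.segment_lengths, self.com_distances)):
            if not (L > 0):
                raise ConfigurationError(f"segment_lengths[{i}]: must be > 0, got {L}")
            if not (0 < Lc <= L):
                raise ConfigurationError(
                    f"com_distances[{i}]: must satisfy 0 < Lc <= L, got {Lc}")
        for name in ("masses", "inertias"):
            for i, v in enumerate(getattr(self, name)):
                if not (v > 0):
                    raise ConfigurationError(f"{name}[{i}]: must be > 0, got {v}")
        if len(self.gravity) != 2:
            raise ConfigurationError("gravity: must be a planar 2-vector")
        if self.joint_damping:
            if len(self.joint_damping) != n:
                raise ConfigurationError(
                    f"joint_damping: expected {n} entries, "
                    f"got {len(self.joint_damping)}")
            for i, v in enumerate(self.joint_damping):
                if v < 0:
                    raise ConfigurationError(
                        f"joint_damping[{i}]: must be >= 0, got {v}")
        if len(self.f_max) != self.n_muscles:
            raise ConfigurationError(
                f"f_max: expected {self.n_muscles} entries, got {len(self.f_max)}")
        for i, v in enumerate(self.f_max):
            if not (v > 0):
                raise ConfigurationError(f"f_max[{i}]: must be > 0, got {v}")
        for mus in self.muscles:
            segs = {seg for seg, _ in mus.points}
            if not all(0 <= seg <= n for seg in segs):
                raise ConfigurationError(
                    f"muscle {mus.name!r}: segment index out of range 0..{n}")
            if len(segs) < 2:
                raise ConfigurationError(
                    f"muscle {mus.name!r}: must span at least one joint "
                    "(attachments on a single segment)")

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


@dataclass
class ModelState:
    """Joint angles ``q`` [rad], velocities ``qdot`` [rad/s] and time [s]."""

    q: np.ndarray
    qdot: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float).reshape(-1)
        self.qdot = np.asarray(self.qdot, dtype=float).reshape(-1)
        if self.q.shape != self.qdot.shape:
            raise InvalidInputError("q and qdot must have the same length")
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.qdot))):
            raise InvalidInputError("state contains non-finite entries")


@dataclass(frozen=True)
class DynamicsEval:
    """Joint-space inertia ``M`` [kg m^2] and generalized bias force ``f``
    [N m] in the convention ``M qdd + f = tau``."""

    M: np.ndarray
    f: np.ndarray


@dataclass(frozen=True)
class MuscleKinematicsEval:
    """Musculotendon lengths ``lm`` [m], moment-arm matrix ``R = d lm/d q``
    [m] (m x n, tall) and its time derivative ``Rdot`` [m/s]."""

    lm: np.ndarray
    R: np.ndarray
    Rdot: np.ndarray


@dataclass(frozen=True)
class TaskKinematicsEval:
    """End-effector position ``xt`` [m], task Jacobian ``Jt`` [d x n] and
    its time derivative ``Jtdot``."""

    xt: np.ndarray
    Jt: np.ndarray
    Jtdot: np.ndarray


class _CompiledModel:
    """All model quantities compiled into one function (shared CSE) with a
    cache for the most recent evaluation state."""

    def __init__(self, q_syms, qd_syms, exprs: dict):
        self._names = list(exprs)
        self._fn = sp.lambdify((q_syms, qd_syms), list(exprs.values()),
                               modules="numpy", cse=True)
        self._key = None
        self._values = None

    def __call__(self, name, qv, qdv):
        key = (tuple(np.asarray(qv, float)), tuple(np.asarray(qdv, float)))
        if key != self._key:
            # degenerate geometry (zero-length path edges) yields inf/nan
            # here and is rejected by explicit validation downstream
            with np.errstate(divide="ignore", invalid="ignore"):
                self._values = [np.asarray(v, dtype=float)
                                for v in self._fn(key[0], key[1])]
            self._key = key
        return self._values[self._names.index(name)]


class PlanarArm:
    """Compiled planar linkage model; construct via :func:`build_planar_arm`."""

    def __init__(self, params: ModelParameters, funcs: dict,
                 reference_posture: np.ndarray):
        self.params = params
        self.n_joints = params.n_joints
        self.n_muscles = params.n_muscles
        self.muscle_names = [m.name for m in params.muscles]
        self.f_max = np.asarray(params.f_max, dtype=float)
        self.reference_posture = np.asarray(reference_posture, dtype=float)
        self._f = funcs

    def _zeros(self, qd):
        return np.zeros(self.n_joints) if qd is None else qd

    # -- raw evaluators -------------------------------------------------
    # quantities that do not depend on qd accept it anyway, so hot loops
    # can keep one cached evaluation per state
    def mass_matrix(self, q, qd=None) -> np.ndarray:
        return self._f("M", q, self._zeros(qd))

    def bias_force(self, q, qd) -> np.ndarray:
        return self._f("bias", q, qd).reshape(-1)

    def potential_energy(self, q) -> float:
        return float(self._f("V", q, np.zeros(self.n_joints)))

    def total_energy(self, state: ModelState) -> float:
        """Hamiltonian ``0.5 qd' M qd + V(q)`` — conserved when unforced."""
        M = self.mass_matrix(state.q)
        return 0.5 * state.qdot @ M @ state.qdot + self.potential_energy(state.q)

    def muscle_lengths(self, q, qd=None) -> np.ndarray:
        return self._f("lm", q, self._zeros(qd)).reshape(-1)

    def moment_arm(self, q, qd=None) -> np.ndarray:
        return self._f("R", q, self._zeros(qd))

    def moment_arm_dot(self, q, qd) -> np.ndarray:
        return self._f("Rdot", q, qd)

    def task_position(self, q, qd=None) -> np.ndarray:
        return self._f("xt", q, self._zeros(qd)).reshape(-1)

    def task_jacobian(self, q, qd=None) -> np.ndarray:
        return self._f("Jt", q, self._zeros(qd))

    def task_jacobian_dot(self, q, qd) -> np.ndarray:
        return self._f("Jtdot", q, qd)

    def joint_positions(self, q) -> np.ndarray:
        """World positions of joints 1..n plus the chain tip; shape (n+1, 2)."""
        return self._f("joints", q, np.zeros(self.n_joints)).reshape(-1, 2)

    def com_positions(self, q) -> np.ndarray:
        return self._f("coms", q, np.zeros(self.n_joints)).reshape(-1, 2)

    def com_accelerations(self, q, qd, qdd) -> np.ndarray:
        """Center-of-mass accelerations, shape (n, 2): ``Jc qdd + Jcdot qd``."""
        Jc = self._f("com_jac", q, qd)
        Jcdot = self._f("com_jac_dot", q, qd)
        acc = Jc @ np.asarray(qdd, float) + Jcdot @ np.asarray(qd, float)
        return acc.reshape(-1, 2)

    def muscle_path_points(self, q):
        """World coordinates of every muscle path point.

        Returns a list (one entry per muscle) of arrays (K_i, 2), plus the
        host segment index of each point, as ``(points, hosts)``.
        """
        flat = self._f("mus_pts", q, np.zeros(self.n_joints)).reshape(-1, 2)
        points, hosts = [], []
        i = 0
        for mus in self.params.muscles:
            k = len(mus.points)
            points.append(flat[i:i + k])
            hosts.append([seg for seg, _ in mus.points])
            i += k
        return points, hosts


def _world_point(joint_pos, thetas, seg, xy):
    """Symbolic world position of a local point on a segment (0 = ground)."""
    x, y = sp.Float(xy[0]), sp.Float(xy[1])
    if seg == 0:
        return sp.Matrix([x, y])
    th = thetas[seg - 1]
    c, s = sp.cos(th), sp.sin(th)
    base = joint_pos[seg - 1]
    return sp.Matrix([base[0] + c * x - s * y, base[1] + s * x + c * y])


def build_planar_arm(params: ModelParameters,
                     reference_posture=None) -> PlanarArm:
    """Symbolically derive and compile a planar arm model.

    All dynamic and kinematic quantities are closed-form functions obtained
    by differentiating the linkage Lagrangian and the polyline muscle path
    lengths.  The moment-arm matrix is required to have full column rank at
    the reference posture; parameter sets violating this are rejected with
    the offending muscles named.
    """
    params.validate()
    n = params.n_joints
    q = sp.symbols(f"q0:{n}", real=True)
    qd = sp.symbols(f"qd0:{n}", real=True)

    thetas = [sp.Add(*q[:k + 1]) for k in range(n)]
    # joint k position (k = 0..n-1) and chain tip (index n)
    joint_pos = [sp.Matrix([0, 0])]
    for k in range(n):
        L = params.segment_lengths[k]
        joint_pos.append(joint_pos[k] +
                         sp.Matrix([L * sp.cos(thetas[k]), L * sp.sin(thetas[k])]))
    coms = []
    for k in range(n):
        Lc = params.com_distances[k]
        coms.append(joint_pos[k] +
                    sp.Matrix([Lc * sp.cos(thetas[k]), Lc * sp.sin(thetas[k])]))

    qd_vec = sp.Matrix(qd)
    kinetic = sp.S.Zero
    for k in range(n):
        v = coms[k].jacobian(q) * qd_vec
        omega = sp.Add(*qd[:k + 1])
        kinetic += (sp.Rational(1, 2) * params.masses[k] * (v.T * v)[0, 0]
                    + sp.Rational(1, 2) * params.inertias[k] * omega**2)
    kinetic = sp.expand(kinetic)
    gx, gy = params.gravity
    potential = sp.Add(*[-params.masses[k] * (gx * coms[k][0] + gy * coms[k][1])
                         for k in range(n)])

    M_sym = sp.hessian(kinetic, qd)
    # bias f = Mdot qd - dT/dq + dV/dq   (so that M qdd + f = tau)
    Mdot = sp.zeros(n, n)
    for k in range(n):
        Mdot += M_sym.diff(q[k]) * qd[k]
    grad_T = sp.Matrix([kinetic.diff(qk) for qk in q])
    grad_V = sp.Matrix([potential.diff(qk) for qk in q])
    damping = (params.joint_damping if params.joint_damping
               else (0.0,) * n)
    bias = (Mdot * qd_vec - grad_T + grad_V
            + sp.Matrix([damping[k] * qd[k] for k in range(n)]))

    # muscle path lengths: each edge is measured in the frame of its
    # proximal host segment, so the expression only involves the joints
    # the edge actually spans (usually one) and stays compact
    def point_in_frame(frame, seg, xy):
        # position of a point fixed on `seg`, expressed in `frame` <= seg
        p = sp.Matrix([sp.Float(xy[0]), sp.Float(xy[1])])
        for k in range(seg, frame, -1):
            c, s = sp.cos(q[k - 1]), sp.sin(q[k - 1])
            p = sp.Matrix([c * p[0] - s * p[1], s * p[0] + c * p[1]])
            off = params.segment_lengths[k - 2] if k - 1 >= 1 else 0.0
            p[0] = p[0] + off
        return p

    lm_exprs = []
    all_pts = []
    for mus in params.muscles:
        all_pts.extend(_world_point(joint_pos, thetas, seg, xy)
                       for seg, xy in mus.points)
        length = sp.S.Zero
        for (sa, xya), (sb, xyb) in zip(mus.points[:-1], mus.points[1:]):
            lo, hi = (sa, sb) if sa <= sb else (sb, sa)
            xy_lo, xy_hi = (xya, xyb) if sa <= sb else (xyb, xya)
            pa = point_in_frame(lo, lo, xy_lo)
            pb = point_in_frame(lo, hi, xy_hi)
            d = pb - pa
            length += sp.sqrt(d[0]**2 + d[1]**2)
        lm_exprs.append(length)
    lm_vec = sp.Matrix(lm_exprs)
    R_sym = lm_vec.jacobian(q)
    Rdot_sym = sp.zeros(*R_sym.shape)
    for k in range(n):
        Rdot_sym += R_sym.diff(q[k]) * qd[k]

    xt = joint_pos[n]
    Jt_sym = xt.jacobian(q)
    Jtdot_sym = sp.zeros(*Jt_sym.shape)
    for k in range(n):
        Jtdot_sym += Jt_sym.diff(q[k]) * qd[k]

    com_stack = sp.Matrix.vstack(*coms)          # (2n, 1)
    com_jac = com_stack.jacobian(q)              # (2n, n)
    com_jac_dot = sp.zeros(*com_jac.shape)
    for k in range(n):
        com_jac_dot += com_jac.diff(q[k]) * qd[k]

    funcs = _CompiledModel(q, qd, {
        "M": M_sym,
        "bias": bias,
        "V": potential,
        "lm": lm_vec,
        "R": R_sym,
        "Rdot": Rdot_sym,
        "xt": xt,
        "Jt": Jt_sym,
        "Jtdot": Jtdot_sym,
        "joints": sp.Matrix.vstack(*joint_pos[1:]),
        "coms": com_stack,
        "com_jac": com_jac,
        "com_jac_dot": com_jac_dot,
        "mus_pts": sp.Matrix.vstack(*all_pts),
    })

    if reference_posture is None:
        reference_posture = np.zeros(n)
    reference_posture = np.asarray(reference_posture, dtype=float)
    model = PlanarArm(params, funcs, reference_posture)
    _validate_geometry(model)
    return model


def _validate_geometry(model: PlanarArm) -> None:
    q_ref = model.reference_posture
    points, _ = model.muscle_path_points(q_ref)
    for mus, pts in zip(model.params.muscles, points):
        seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg_len < 1e-9):
            raise GeometryError(
                f"muscle {mus.name!r}: coincident path points at the "
                "reference posture (zero-length segment)")
    R = model.moment_arm(q_ref)
    s = np.linalg.svd(R, compute_uv=False)
    rank = int(np.sum(s > 1e-10 * max(s[0], 1.0)))
    if rank < model.n_joints:
        row_norm = np.linalg.norm(R, axis=1)
        weak = [name for name, rn in zip(model.muscle_names, row_norm)
                if rn < 1e-10]
        raise ConfigurationError(
            f"moment-arm matrix rank {rank} < {model.n_joints} at the "
            f"reference posture; muscles with zero moment arm: {weak or 'none'}")


def default_arm_parameters() -> ModelParameters:
    """Parameters of the bundled 3-joint, 9-muscle planar arm.

    Segment lengths/masses approximate a 50th-percentile adult arm
    (upper arm, forearm, hand).  Six mono-articular muscles form
    antagonist pairs across the three joints; three bi-articular muscles
    span the shoulder-elbow (both sides) and elbow-wrist joints.  The
    muscle on the habitually-stretched side of each joint is routed
    through a pair of via-points close to the joint (one per adjacent
    segment, at unequal radii), emulating an anatomical pulley: this
    keeps its moment arm useful up to ~2.3 rad of flexion, where a plain
    straight-line path would cross the joint center, and the unequal via
    radii guarantee the path length can never degenerate to zero.  The
    moment-arm matrix is full rank and every joint can be torqued in
    both directions throughout the reaching workspace.  Gravity defaults
    to zero (posture and reaching experiments are gravity-free unless
    configured otherwise).
    """
    L1, L2, L3 = 0.33, 0.31, 0.18

    def via_pair(parent, child, Lp, side, name):
        # pulley-like routing close to the joint; via radii differ so the
        # inter-via path segment never collapses
        s = float(side)
        rhoP, d2P = 0.0578, 0.013
        rhoC, d2C = 0.0468, 0.015
        xo = (Lp - 0.10) if parent else -0.10
        xv = (Lp - d2P) if parent else -d2P
        return MusclePath(name, (
            (parent, (xo, s * 0.045)),
            (parent, (xv, s * rhoP)),
            (child, (d2C, s * rhoC)),
            (child, (0.10, s * 0.03)),
        ))

    def plain(parent, child, Lp, side, name, dP=0.065, dC=0.035, h=0.025):
        s = float(side)
        xo = (Lp - dP) if parent else -dP
        return MusclePath(name, ((parent, (xo, s * h)), (child, (dC, s * h))))

    muscles = (
        via_pair(0, 1, None, +1, "sh_flex"),
        plain(0, 1, None, -1, "sh_ext"),
        plain(1, 2, L1, +1, "el_flex", dP=0.08, dC=0.05),
        via_pair(1, 2, L1, -1, "el_ext"),
        plain(2, 3, L2, +1, "wr_flex", dP=0.08, dC=0.05),
        via_pair(2, 3, L2, -1, "wr_ext"),
        MusclePath("bi_sh_el_flex", ((0, (-0.06, 0.045)), (2, (0.07, 0.045)))),
        MusclePath("bi_el_wr_flex", ((1, (L1 - 0.06, 0.045)), (3, (0.07, 0.045)))),
        MusclePath("bi_sh_el_ext", ((0, (-0.06, -0.055)), (1, (L1 - 0.02, -0.055)),
                                    (2, (0.07, -0.045)))),
    )
    return ModelParameters(
        segment_lengths=(L1, L2, L3),
        com_distances=(0.15, 0.14, 0.08),
        masses=(2.0, 1.3, 0.4),
        inertias=(0.0182, 0.0104, 0.0011),
        muscles=muscles,
        f_max=(1200.0, 1200.0, 800.0, 800.0, 400.0, 400.0, 600.0, 500.0, 600.0),
        gravity=(0.0, 0.0),
        # passive tissue damping; also keeps the unregulated task-null
        # joint motion of operational-space control well-behaved
        joint_damping=(0.4, 0.3, 0.1),
    )


def evaluate_dynamics(model: PlanarArm, state: ModelState,
                      external_torque=None) -> DynamicsEval:
    """Evaluate ``M`` and the bias force ``f`` at a state.

    ``f`` aggregates Coriolis/centrifugal and gravity terms minus any
    externally applied generalized load, so that ``M qdd + f = tau`` with
    ``tau`` the actuation torque.
    """
    if state.q.shape[0] != model.n_joints:
        raise InvalidInputError(
            f"state dimension {state.q.shape[0]} != model DoFs {model.n_joints}")
    M = model.mass_matrix(state.q)
    f = model.bias_force(state.q, state.qdot)
    if external_torque is not None:
        ext = np.asarray(external_torque, dtype=float).reshape(-1)
        if ext.shape[0] != model.n_joints:
            raise InvalidInputError("external_torque dimension mismatch")
        f = f - ext
    return DynamicsEval(M=M, f=f)


def evaluate_muscle_kinematics(model: PlanarArm,
                               state: ModelState) -> MuscleKinematicsEval:
    """Musculotendon lengths, moment arms and their time derivative."""
    if state.q.shape[0] != model.n_joints:
        raise InvalidInputError("state dimension mismatch")
    return MuscleKinematicsEval(
        lm=model.muscle_lengths(state.q),
        R=model.moment_arm(state.q),
        Rdot=model.moment_arm_dot(state.q, state.qdot),
    )


def evaluate_task_kinematics(model: PlanarArm,
                             state: ModelState) -> TaskKinematicsEval:
    """End-effector position, task Jacobian and its time derivative."""
    if state.q.shape[0] != model.n_joints:
        raise InvalidInputError("state dimension mismatch")
    return TaskKinematicsEval(
        xt=model.task_position(state.q),
        Jt=model.task_jacobian(state.q),
        Jtdot=model.task_jacobian_dot(state.q, state.qdot),
    )
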