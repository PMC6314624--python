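"""Feasible muscle-force polytopes: construction, vertex enumeration, sampling.

A particular muscle-force solution ``fm_par`` realizing a joint torque is
generally not physiological (entries may be negative or exceed the
muscle's capacity).  The physiological solutions form

    fm = fm_par + N_TR fm0,      lo <= fm <= hi,

a convex polytope in the moment-arm null space.  Writing ``fm0 = B y``
with ``B`` an orthonormal basis of range(N_TR) (dimension ``r = m - n``)
turns the bounds into the full-column-rank halfspace system

    [ B; -B ] y  <=  [ hi - fm_par; fm_par - lo ]       (2m rows),

which is bounded whenever feasible.  Vertices are enumerated by two
backends behind one contract — a bespoke combinatorial brute force
(reference oracle: intersect every r-subset of hyperplanes, keep
feasible points) and Qhull's halfspace intersection (production) — and
the polytope is sampled by recursive midpoint interpolation between the
vertices, which stays inside the set by convexity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog, minimize
from scipy.spatial import HalfspaceIntersection, QhullError

from .exceptions import (CapacityError, InfeasiblePolytopeError,
                         InvalidInputError, UnboundedPolytopeError)
from .linalg import DEFAULT_RTOL
from .model import ModelState, PlanarArm
from .projections import muscle_projection, muscle_force_map

__all__ = [
    "MuscleModelSpec", "Halfspaces", "VertexSet", "FeasibleForceSet",
    "ForceSpaceSummary", "build_force_inequalities", "enumerate_vertices",
    "sample_polytope", "feasible_force_set", "force_space_summary",
    "min_norm_point", "chebyshev_center",
]


# ---------------------------------------------------------------------------
# muscle models
# ---------------------------------------------------------------------------

def _default_fl(lnorm):
    """Synthetic bell-shaped force-length gain (stand-in curve)."""
    return np.exp(-((lnorm - 1.0) / 0.45) ** 2)


def _default_fv(vnorm):
    """Synthetic sigmoidal force-velocity gain (stand-in curve):
    ~0.2 at fast shortening, 1 isometric, ~1.5 at fast lengthening."""
    return 0.2 + 1.3 / (1.0 + np.exp(-4.0 * np.asarray(vnorm, float)))


def _default_fpe(lnorm):
    """Synthetic exponential passive force (fraction of f_max; stand-in)."""
    return 0.05 * np.maximum(np.exp(8.0 * (np.asarray(lnorm, float) - 1.0)) - 1.0, 0.0)


@dataclass(frozen=True)
class MuscleModelSpec:
    """Affine-in-activation muscle force model defining force bounds.

    The linear model is ``fm = f_max o am`` with activations in [0, 1],
    so ``0 <= fm <= f_max``.  The hill-type hook generalizes this to
    ``c0 <= fm <= c1 + c0`` with a state-dependent gain
    ``c1 = f_max o fl o fv`` and passive offset ``c0 = f_max o fpe``;
    the bundled fl/fv/fpe curves are synthetic stand-in shapes and can be
    replaced by user-supplied callables of (lm_norm, lmdot_norm).
    """

    kind: str
    f_max: np.ndarray
    lm_ref: np.ndarray | None = None    # normalizing (optimal) lengths [m]
    fl: object = None
    fv: object = None
    fpe: object = None

    @staticmethod
    def linear(f_max) -> "MuscleModelSpec":
        return MuscleModelSpec(kind="linear",
                               f_max=np.asarray(f_max, dtype=float))

    @staticmethod
    def hill_hook(f_max, lm_ref, fl=None, fv=None, fpe=None) -> "MuscleModelSpec":
        return MuscleModelSpec(
            kind="hill-type-hook",
            f_max=np.asarray(f_max, dtype=float),
            lm_ref=np.asarray(lm_ref, dtype=float),
            fl=fl or _default_fl, fv=fv or _default_fv, fpe=fpe or _default_fpe)

    def bounds(self, lm=None, lmdot=None):
        """Force bounds ``(lo, hi)`` [N] at a muscle kinematic state."""
        if self.kind == "linear":
            return np.zeros_like(self.f_max), self.f_max.copy()
        if self.kind == "hill-type-hook":
            if lm is None:
                raise InvalidInputError("hill-type-hook bounds need lm")
            lnorm = np.asarray(lm, float) / self.lm_ref
            vnorm = (np.zeros_like(lnorm) if lmdot is None
                     else np.asarray(lmdot, float) / self.lm_ref)
            c0 = self.f_max * self.fpe(lnorm)
            c1 = self.f_max * self.fl(lnorm) * self.fv(vnorm)
            return c0, c1 + c0
        raise InvalidInputError(f"unknown muscle model kind {self.kind!r}")


# ---------------------------------------------------------------------------
# halfspace systems
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Halfspaces:
    """H-representation ``Z y <= beta`` in reduced null-space coordinates.

    ``basis`` (m x r, orthonormal columns) maps reduced coordinates back
    to muscle space: ``fm0 = basis @ y``; it is None for standalone
    systems read from file.
    """

    Z: np.ndarray
    beta: np.ndarray
    basis: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "Z", np.atleast_2d(np.asarray(self.Z, float)))
        object.__setattr__(self, "beta", np.asarray(self.beta, float).reshape(-1))
        if self.Z.shape[0] != self.beta.shape[0]:
            raise InvalidInputError("Z and beta row counts differ")

    @property
    def variable_dim(self) -> int:
        return self.Z.shape[1]

    def contains(self, y, tol: float = 1e-9) -> np.ndarray:
        y = np.atleast_2d(np.asarray(y, float))
        return np.all(y @ self.Z.T <= self.beta + tol, axis=1)


@dataclass(frozen=True)
class VertexSet:
    """Extreme points of a bounded halfspace system."""

    vertices: np.ndarray            # (v, r)
    dedup_tol: float = 1e-9
    feasible: bool = True


def build_force_inequalities(fm_par, muscle_model: MuscleModelSpec,
                             N_TR: np.ndarray, lm=None, lmdot=None,
                             rank_tol: float = DEFAULT_RTOL) -> Halfspaces:
    """Encode ``lo <= fm_par + N_TR fm0 <= hi`` as ``Z y <= beta``.

    The null projector is first reduced to an orthonormal basis ``B`` of
    its range (rank ``r``), since in full muscle-space coordinates the
    system is trivially unbounded along directions N_TR annihilates.
    Because ``N_TR B = B``, the system becomes ``[B; -B] y <= [hi -
    fm_par; fm_par - lo]`` with ``2m`` rows and full column rank.
    """
    fm_par = np.asarray(fm_par, dtype=float).reshape(-1)
    N_TR = np.atleast_2d(np.asarray(N_TR, float))
    m = fm_par.shape[0]
    if N_TR.shape != (m, m):
        raise InvalidInputError("N_TR must be m x m")
    lo, hi = muscle_model.bounds(lm, lmdot)
    U, s, _ = np.linalg.svd(N_TR)
    r = int(np.sum(s > rank_tol * max(s[0] if s.size else 0.0, 1.0)))
    B = U[:, :r]
    Z = np.vstack([B, -B])
    beta = np.concatenate([hi - fm_par, fm_par - lo])
    return Halfspaces(Z=Z, beta=beta, basis=B)


def chebyshev_center(H: Halfspaces):
    """Center and radius of the largest ball inside ``Z y <= beta``.

    Returns ``(center, radius)``; radius < 0 means the system is
    infeasible, radius 0 a degenerate (lower-dimensional) polytope.
    """
    Z, beta = H.Z, H.beta
    k, r = Z.shape
    norms = np.linalg.norm(Z, axis=1)
    A_ub = np.hstack([Z, norms[:, None]])
    c = np.zeros(r + 1)
    c[-1] = -1.0
    res = linprog(c, A_ub=A_ub, b_ub=beta,
                  bounds=[(None, None)] * r + [(None, None)],
                  method="highs")
    if res.status == 2:
        return None, -np.inf
    if res.status == 3:
        raise UnboundedPolytopeError(
            "halfspace system is unbounded: Z is not full column rank "
            "(boundedness requires a feasible system with full-column-rank Z)")
    if not res.success:
        raise InfeasiblePolytopeError(f"LP failed: {res.message}")
    radius = float(res.x[r])
    if radius < 0:          # even the best center violates some halfspace
        return None, radius
    return res.x[:r], radius


def _assert_bounded(H: Halfspaces) -> None:
    """Raise unless the recession cone of ``Z y <= beta`` is {0}."""
    Z = H.Z
    r = Z.shape[1]
    # direction d with Z d <= 0, ||d||_inf = 1 exists  <=>  unbounded
    for i in range(r):
        for sign in (1.0, -1.0):
            c = np.zeros(r)
            c[i] = -sign
            res = linprog(c, A_ub=Z, b_ub=np.zeros(Z.shape[0]),
                          bounds=[(-1, 1)] * r, method="highs")
            if res.success and -res.fun > 1e-9:
                raise UnboundedPolytopeError(
                    "halfspace system is unbounded along a recession "
                    "direction; a bounded feasible polytope requires Z "
                    "with full column rank")


def _dedup(points: np.ndarray, tol: float) -> np.ndarray:
    """Remove near-duplicate points (absolute tolerance).

    Small sets use exact greedy pairwise comparison; larger ones bin the
    coordinates on a grid of spacing ``tol`` (first occurrence wins, the
    original ordering is preserved).
    """
    if len(points) == 0:
        return points
    if len(points) <= 64:
        kept: list[np.ndarray] = []
        for p in points:
            if not any(np.linalg.norm(p - kk, ord=np.inf) <= tol
                       for kk in kept):
                kept.append(p)
        return np.array(kept)
    keys = np.round(points / max(tol, 1e-15)).astype(np.int64)
    _, idx = np.unique(keys, axis=0, return_index=True)
    return points[np.sort(idx)]


def _vertices_bruteforce(H: Halfspaces, tol: float) -> np.ndarray:
    """Reference oracle: intersect every r-subset of the hyperplanes and
    keep the feasible intersection points."""
    Z, beta = H.Z, H.beta
    k, r = Z.shape
    scale = 1.0 + np.abs(beta).max(initial=0.0)
    out = []
    for idx in itertools.combinations(range(k), r):
        A = Z[list(idx)]
        b = beta[list(idx)]
        if abs(np.linalg.det(A)) < 1e-12:
            continue
        y = np.linalg.solve(A, b)
        if np.all(Z @ y <= beta + 1e-8 * scale):
            out.append(y)
    return np.array(out).reshape(-1, r)


def _vertices_qhull(H: Halfspaces, interior: np.ndarray) -> np.ndarray:
    halfspaces = np.hstack([H.Z, -H.beta[:, None]])
    hs = HalfspaceIntersection(halfspaces, interior)
    return hs.intersections


def enumerate_vertices(H: Halfspaces, backend: str = "auto",
                       dedup_tol: float = 1e-9) -> VertexSet:
    """Convert an H-representation to its vertex set.

    Backends: ``"bruteforce"`` (combinatorial reference oracle) and
    ``"qhull"`` (production).  ``"auto"`` uses Qhull for dimensions >= 2
    with a full-dimensional interior and falls back to brute force for
    1-D or degenerate (flat) polytopes.  Infeasible systems return an
    empty set flagged infeasible; unbounded ones raise.
    """
    center, radius = chebyshev_center(H)
    if center is None:
        return VertexSet(vertices=np.empty((0, H.variable_dim)),
                         dedup_tol=dedup_tol, feasible=False)
    _assert_bounded(H)
    r = H.variable_dim
    if backend == "auto":
        backend = "qhull" if (r >= 2 and radius > 1e-9) else "bruteforce"
    if backend == "qhull":
        try:
            verts = _vertices_qhull(H, center)
        except QhullError:
            verts = _vertices_bruteforce(H, dedup_tol)
    elif backend == "bruteforce":
        verts = _vertices_bruteforce(H, dedup_tol)
    else:
        raise InvalidInputError(f"unknown backend {backend!r}")
    verts = _dedup(np.asarray(verts).reshape(-1, r), dedup_tol)
    return VertexSet(vertices=verts, dedup_tol=dedup_tol, feasible=True)


def sample_polytope(H: Halfspaces, depth: int = 0,
                    backend: str = "auto",
                    dedup_tol: float = 1e-9) -> np.ndarray:
    """Sample a bounded polytope by midpoint interpolation between vertices.

    Depth 0 returns the vertex set; each further iteration adds the
    midpoints (lambda = 0.5) of all distinct point pairs and removes
    duplicates.  Every returned point satisfies the inequalities by
    convexity.
    """
    if depth < 0:
        raise InvalidInputError("depth must be >= 0")
    vset = enumerate_vertices(H, backend=backend, dedup_tol=dedup_tol)
    if not vset.feasible:
        raise InfeasiblePolytopeError("cannot sample an infeasible system")
    pts = vset.vertices
    for _ in range(depth):
        if len(pts) < 2:
            break
        idx = np.array(list(itertools.combinations(range(len(pts)), 2)))
        mids = 0.5 * (pts[idx[:, 0]] + pts[idx[:, 1]])
        pts = _dedup(np.vstack([pts, mids]), dedup_tol)
    return pts


def min_norm_point(H: Halfspaces, tol: float = 1e-9) -> np.ndarray:
    """Minimize ``||y||^2`` subject to ``Z y <= beta`` (projection of the
    origin onto the polytope)."""
    Z, beta = H.Z, H.beta
    if np.all(0.0 <= beta + tol):
        return np.zeros(H.variable_dim)
    center, radius = chebyshev_center(H)
    if center is None:
        raise InfeasiblePolytopeError("min_norm_point: system is infeasible")
    res = minimize(
        lambda y: 0.5 * y @ y, center, jac=lambda y: y,
        constraints=[{"type": "ineq",
                      "fun": lambda y: beta - Z @ y,
                      "jac": lambda y: -Z}],
        method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-12},
    )
    y = res.x
    viol = float(np.max(Z @ y - beta, initial=0.0))
    if not res.success and viol > 1e-6:
        raise InfeasiblePolytopeError(
            f"QP did not converge (violation {viol:.2e}): {res.message}")
    return y


# ---------------------------------------------------------------------------
# feasible force sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeasibleForceSet:
    """All sampled muscle-force realizations of one action at one state."""

    fm_par: np.ndarray              # particular (minimum-norm) solution [N]
    samples: np.ndarray             # (S, m), each = fm_par + N_TR fm0_i
    muscle_model: MuscleModelSpec
    state_tag: float                # time [s]
    halfspaces: Halfspaces = field(repr=False, default=None)
    reduced_samples: np.ndarray = field(repr=False, default=None)
    muscle_names: tuple = ()


def feasible_force_set(model: PlanarArm, state: ModelState, tau,
                       muscle_model: MuscleModelSpec, depth: int = 0,
                       external_torque=None,
                       backend: str = "auto") -> FeasibleForceSet:
    """Compute the feasible muscle-force set realizing a joint torque.

    The particular solution is ``fm_par = -R+' tau``; the feasible set
    adds every sampled null-space correction, each of which reproduces
    the same torque and respects the muscle-model bounds.
    """
    tau = np.asarray(tau, dtype=float).reshape(-1)
    mp = muscle_projection(model, state, external_torque=external_torque)
    fm_par = muscle_force_map(tau, np.zeros(model.n_muscles), mp)
    H = build_force_inequalities(fm_par, muscle_model, mp.N_TR,
                                 lm=mp.lm, lmdot=mp.R @ state.qdot)
    try:
        ys = sample_polytope(H, depth=depth, backend=backend)
        y_min = min_norm_point(H)
    except InfeasiblePolytopeError as err:
        raise CapacityError(
            "task infeasible under muscle bounds: no null-space correction "
            "brings the particular solution inside the force limits") from err
    # the minimum-norm (least co-contraction) solution leads the sample list
    ys = _dedup(np.vstack([y_min[None, :], ys]), 1e-9)
    samples = fm_par[None, :] + ys @ H.basis.T
    return FeasibleForceSet(
        fm_par=fm_par, samples=samples, muscle_model=muscle_model,
        state_tag=state.time, halfspaces=H, reduced_samples=ys,
        muscle_names=tuple(model.muscle_names))


@dataclass(frozen=True)
class ForceSpaceSummary:
    """Box-plot statistics and inter-muscle correlations of a force set."""

    stats: "object"                 # pandas DataFrame: per-muscle quantiles
    correlation: np.ndarray         # (m, m) Pearson, undefined entries 0
    undefined: np.ndarray           # (m, m) bool mask of undefined entries


def force_space_summary(fset: FeasibleForceSet) -> ForceSpaceSummary:
    """Per-muscle min/quartiles/median/max and the Pearson correlation
    matrix across samples.

    Muscles with zero force variance across the samples have no defined
    correlation; those entries are flagged in ``undefined`` and set to 0
    rather than propagating NaN.
    """
    import pandas as pd

    X = np.asarray(fset.samples, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InvalidInputError("force_space_summary needs >= 2 samples")
    names = list(fset.muscle_names) or [f"m{i}" for i in range(X.shape[1])]
    stats = pd.DataFrame({
        "min": X.min(axis=0),
        "q1": np.percentile(X, 25, axis=0),
        "median": np.median(X, axis=0),
        "q3": np.percentile(X, 75, axis=0),
        "max": X.max(axis=0),
    }, index=names)
    sd = X.std(axis=0)
    degenerate = sd < 1e-12
    m = X.shape[1]
    corr = np.zeros((m, m))
    undefined = np.zeros((m, m), dtype=bool)
    ok = ~degenerate
    if ok.any():
        sub = np.corrcoef(X[:, ok], rowvar=False)
        sub = np.atleast_2d(sub)
        ii = np.where(ok)[0]
        corr[np.ix_(ii, ii)] = sub
    undefined[degenerate, :] = True
    undefined[:, degenerate] = True
    np.fill_diagonal(corr, np.where(degenerate, 0.0, 1.0))
    return ForceSpaceSummary(stats=stats, correlation=corr, undefined=undefined)
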