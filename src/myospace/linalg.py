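"""Moore-Penrose pseudoinverse and orthogonal projection operators.

For a real matrix ``A`` (m x n) the four orthogonal projectors are

* ``T = A A+``      — projector onto the column space C(A),
* ``F = A+ A``      — projector onto the row space R(A),
* ``N_T = I - T``   — projector onto the left null space N(A^T),
* ``N_F = I - F``   — projector onto the (right) null space N(A).

All four are built from a single singular value decomposition with an
explicit relative rank cutoff, so that rank-deficient matrices yield
exact idempotent/symmetric projectors instead of silently ill-conditioned
ones.  The general solution of a consistent underdetermined system
``A x = b`` decomposes into a minimum-norm particular solution
``x_par = A+ b`` in R(A) and an arbitrary homogeneous part
``x_perp = N_F x0`` in N(A); the two are orthogonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InconsistentSystemError, InvalidInputError

__all__ = ["ProjectorBundle", "pseudoinverse", "projectors", "decompose_solution",
           "read_matrix"]

#: Relative singular-value cutoff below which directions are treated as null.
DEFAULT_RTOL = 1e-10


def _check_matrix(A: np.ndarray) -> np.ndarray:
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.ndim != 2:
        raise InvalidInputError(f"expected a 2-D matrix, got ndim={A.ndim}")
    if not np.all(np.isfinite(A)):
        raise InvalidInputError("matrix contains non-finite entries")
    return A


@dataclass(frozen=True)
class ProjectorBundle:
    """The pseudoinverse and all four projection operators of a matrix.

    Computed once from a single SVD and cached; recomputation from the
    same matrix is value-identical.
    """

    source_matrix: np.ndarray
    pinv: np.ndarray
    range_projector: np.ndarray       # T = A A+   (m x m)
    row_projector: np.ndarray         # F = A+ A   (n x n)
    left_null_projector: np.ndarray   # N_T = I - T
    right_null_projector: np.ndarray  # N_F = I - F
    rank: int
    rtol: float = field(default=DEFAULT_RTOL)

    @property
    def T(self) -> np.ndarray:
        return self.range_projector

    @property
    def F(self) -> np.ndarray:
        return self.row_projector

    @property
    def N_T(self) -> np.ndarray:
        return self.left_null_projector

    @property
    def N_F(self) -> np.ndarray:
        return self.right_null_projector


def _svd_pinv(A: np.ndarray, rtol: float):
    U, s, Vt = np.linalg.svd(A, full_matrices=True)
    if s.size and s[0] > 0:
        cutoff = rtol * s[0]
    else:
        cutoff = np.inf
    rank = int(np.sum(s > cutoff))
    s_inv = np.zeros_like(s)
    s_inv[:rank] = 1.0 / s[:rank]
    pinv = (Vt[:rank].T * s_inv[:rank]) @ U[:, :rank].T
    return U, s, Vt, rank, pinv


def pseudoinverse(A: np.ndarray, rtol: float = DEFAULT_RTOL) -> np.ndarray:
    """Moore-Penrose pseudoinverse ``A+`` of a real matrix.

    Singular values below ``rtol * sigma_max`` are treated as zero.  The
    result satisfies the four Penrose conditions; for a full-row-rank
    matrix ``A A+ = I`` (right inverse), for full column rank ``A+ A = I``
    (left inverse), and ``x = A+ b`` is the least-squares/minimum-norm
    solution of ``A x = b``.
    """
    A = _check_matrix(A)
    if rtol <= 0:
        raise InvalidInputError("rtol must be positive")
    return _svd_pinv(A, rtol)[4]


def projectors(A: np.ndarray, rtol: float = DEFAULT_RTOL) -> ProjectorBundle:
    """Build all four orthogonal projectors of ``A`` from one SVD.

    ``T`` and ``F`` are constructed as ``Ur Ur^T`` and ``Vr Vr^T`` from the
    retained singular subspaces, which makes symmetry exact and idempotence
    hold to rounding error; the null projectors are their complements, so
    ``F + N_F = I`` holds exactly as constructed.
    """
    A = _check_matrix(A)
    if rtol <= 0:
        raise InvalidInputError("rtol must be positive")
    m, n = A.shape
    U, s, Vt, rank, pinv = _svd_pinv(A, rtol)
    Ur = U[:, :rank]
    Vr = Vt[:rank].T
    T = Ur @ Ur.T
    F = Vr @ Vr.T
    # enforce exact symmetry against rounding in the outer products
    T = 0.5 * (T + T.T)
    F = 0.5 * (F + F.T)
    return ProjectorBundle(
        source_matrix=A,
        pinv=pinv,
        range_projector=T,
        row_projector=F,
        left_null_projector=np.eye(m) - T,
        right_null_projector=np.eye(n) - F,
        rank=rank,
        rtol=rtol,
    )


def decompose_solution(
    A: np.ndarray,
    b: np.ndarray,
    x0: np.ndarray | None = None,
    rtol: float = DEFAULT_RTOL,
    consistency_tol: float = 1e-8,
):
    """Split the general solution of ``A x = b`` into particular + null parts.

    Returns ``(x_par, x_perp)`` with ``x_par = A+ b`` (minimum-norm exact
    solution) and ``x_perp = N_F x0`` (projection of the free vector onto
    the null space).  The two are orthogonal and ``A (x_par + x_perp) = b``.

    Raises
    ------
    InconsistentSystemError
        If ``b`` is not in the range of ``A``:
        ``||(I - T) b|| > consistency_tol * (1 + ||b||)``.
    """
    A = _check_matrix(A)
    b = np.asarray(b, dtype=float).reshape(-1)
    if b.shape[0] != A.shape[0]:
        raise InvalidInputError(
            f"b has length {b.shape[0]}, expected {A.shape[0]}")
    bundle = projectors(A, rtol=rtol)
    residual = float(np.linalg.norm(b - bundle.T @ b))
    if residual > consistency_tol * (1.0 + np.linalg.norm(b)):
        raise InconsistentSystemError(
            f"A x = b is inconsistent: ||(I - T) b|| = {residual:.3e}",
            residual=residual,
        )
    if x0 is None:
        x0 = np.zeros(A.shape[1])
    x0 = np.asarray(x0, dtype=float).reshape(-1)
    if x0.shape[0] != A.shape[1]:
        raise InvalidInputError(
            f"x0 has length {x0.shape[0]}, expected {A.shape[1]}")
    x_par = bundle.pinv @ b
    x_perp = bundle.N_F @ x0
    return x_par, x_perp


def read_matrix(path) -> np.ndarray:
    """Read a matrix from a plain-text file (whitespace- or comma-separated)."""
    with open(path) as fh:
        text = fh.read()
    delimiter = "," if "," in text.splitlines()[0] else None
    return np.atleast_2d(np.loadtxt(text.splitlines(), delimiter=delimiter))
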