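"""Projection operators and the general solution of an underdetermined system.

Builds the four orthogonal projectors of a wide matrix and splits the
solution of A x = b into a minimum-norm particular part (row space) and a
free homogeneous part (null space).
"""

import numpy as np

from myospace import decompose_solution, projectors

A = np.array([[1.0, 1.0, 0.0],
              [0.0, 1.0, 1.0]])      # 2 equations, 3 unknowns
b = np.array([1.0, 2.0])

bundle = projectors(A)
print("rank(A) =", bundle.rank)
print("row projector F = A+ A:\n", np.round(bundle.F, 3))
print("null projector N_F = I - F:\n", np.round(bundle.N_F, 3))
print("A @ N_F (annihilation, ~0):", np.abs(A @ bundle.N_F).max())

x_par, x_perp = decompose_solution(A, b, x0=np.array([1.0, 0.0, 0.0]))
print("\nparticular solution x_par = A+ b      :", np.round(x_par, 4))
print("null-space component  x_perp = N_F x0 :", np.round(x_perp, 4))
print("orthogonal (x_par . x_perp ~ 0)       :", abs(x_par @ x_perp))
print("A (x_par + x_perp) = b                :", A @ (x_par + x_perp))
# x_par is the unique minimum-norm solution; adding any x_perp from the
# null space changes x without changing A x — the algebraic template for
# kinematic and muscle redundancy.
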