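"""The feasible muscle-force polytope: enumeration, sampling, statistics.

First the printed 3-D worked example (a cube), then the feasible force
set of the bundled arm holding a torque, with box-plot statistics and
the inter-muscle correlation structure.
"""

import numpy as np

import myospace as ms
from myospace.polytope import (Halfspaces, enumerate_vertices,
                               feasible_force_set, force_space_summary,
                               sample_polytope)

# worked example: 6 halfspaces bounding |x_i| <= 0.5
A = np.array([[0, 0, -1], [0, -1, 0], [1, 0, 0],
              [-1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
H = Halfspaces(Z=A, beta=np.full(6, 0.5))
vs = enumerate_vertices(H)
print("cube vertices (%d):" % len(vs.vertices))
print(np.round(sorted(map(tuple, vs.vertices)), 2))
for d in (0, 1, 2):
    print(f"samples at interpolation depth {d}: {len(sample_polytope(H, d))}")
# depth 0 = the 8 corners; each depth adds midpoints of all point pairs,
# filling the polytope while staying inside it by convexity.

# feasible muscle forces of the arm holding a 2 N m shoulder torque
model = ms.build_planar_arm(ms.default_arm_parameters(),
                            reference_posture=ms.default_initial_posture())
mm = ms.MuscleModelSpec.linear(model.f_max)
state = ms.ModelState(q=model.reference_posture, qdot=np.zeros(3))
tau = np.array([2.0, -1.0, 0.3])
fset = feasible_force_set(model, state, tau, mm, depth=1)
R = model.moment_arm(state.q)
print("\narm: %d feasible force samples, torque error %.1e N m"
      % (len(fset.samples), np.abs(-fset.samples @ R - tau).max()))
summ = force_space_summary(fset)
print("\nper-muscle force range [N] (min / median / max):")
print(summ.stats[["min", "median", "max"]].round(1))
print("\ncorrelation sh_flex vs sh_ext: %.2f"
      % summ.correlation[0, 1])
# wide ranges mean the task constrains that muscle loosely; correlations
# reveal which muscles trade off (negative) or co-contract (positive)
# purely through the moment-arm null-space structure.
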