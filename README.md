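# myospace

Null-space projections for redundant musculoskeletal systems: task-,
joint- and muscle-space equations of motion of planar linkage models,
feasible muscle-force polytopes, and reflex/task-space controllers in a
mixed-dynamics simulation scheme.

## The problem

A musculoskeletal limb is redundant twice over.  **Kinematically**: a
low-dimensional task (hand position, d = 2) is produced by more joints
(n = 3), so infinitely many joint motions realize the same hand path.
**Dynamically**: more muscles (m = 9) than joints pull on the skeleton,
so infinitely many muscle-force patterns produce the same joint torques.
Classical muscle-force estimation collapses this freedom with an
optimization criterion (e.g. minimum effort) and reports a single
solution.  That is a modeling choice, not a fact about the limb — and
quantities that depend on the *whole* force distribution, such as joint
reaction loads or co-contraction, can be badly misjudged by it.

`myospace` instead characterizes the *entire* solution space using
null-space projections, for researchers in biomechanics and motor
control who want feasibility sets rather than point estimates.

## The model

Joint-space dynamics `M(q) q̈ + f(q, q̇) = τ` are mapped onto:

- **task space** (`x_t = g(q)`, Jacobian `J_t`):
  `Λ_t (ẍ_t + b_t) + J̄_tᵀ f = f_t`, with task inertia
  `Λ_t = (J_t M⁻¹ J_tᵀ)⁻¹`, bias `b_t = −J̇_t q̇`, and the *dynamically
  consistent* inverse `J̄_tᵀ = Λ_t J_t M⁻¹` — the unique generalized
  inverse through which null-space torques cause zero task acceleration;

- **muscle space** (lengths `l_m(q)`, moment arms `R = ∂l_m/∂q`, force
  map `τ = −Rᵀ f_m`):
  `−Λ_m (l̈_m + b_m) − R⁺ᵀ f = f_m∥ + N_TR f_m0`, with
  `Λ_m = (R M⁻¹ Rᵀ)⁺` and the moment-arm null projector
  `N_TR = I − R R⁺`.  Any `N_TR f_m0` changes muscle co-contraction
  without changing torque or movement.

With muscle-force bounds `lo ≼ f_m ≼ hi`, the feasible forces realizing
a torque form `f_m⊕ = { f_m∥ + N_TR f_m0 : Z f_m0 ≼ β }` — a particular
solution plus a convex polytope, which the package builds (reduced to a
full-rank basis of the null space), vertex-enumerates (brute-force
oracle and Qhull backends behind one contract), and samples by recursive
midpoint interpolation.

Everything runs on a built-in analytic planar arm (3 DoFs, 9 muscles,
symbolic Lagrangian dynamics and polyline muscle paths, so all
derivatives are exact) — see `docs/methods.md` for the model's
assumptions and parameter choices.

## Worked example

```python
import numpy as np
import myospace as ms
from myospace.polytope import feasible_force_set, force_space_summary

model = ms.build_planar_arm(ms.default_arm_parameters(),
                            reference_posture=ms.default_initial_posture())
mm = ms.MuscleModelSpec.linear(model.f_max)
state = ms.ModelState(q=model.reference_posture, qdot=np.zeros(3))

fset = feasible_force_set(model, state, tau=np.array([2.0, -1.0, 0.3]),
                          muscle_model=mm, depth=1)
R = model.moment_arm(state.q)
print(len(fset.samples), np.abs(-fset.samples @ R - [2.0, -1.0, 0.3]).max())
print(force_space_summary(fset).stats[["min", "median", "max"]].round(1).head(3))
```

prints

```
3871 5.062616992290714e-14
         min  median     max
sh_flex -0.0   748.2  1200.0
sh_ext  -0.0   600.0  1200.0
el_flex -0.0    42.0   490.8
```

3871 distinct muscle-force patterns, *every one* reproducing the
commanded torque (2, −1, 0.3) N·m to rounding error while staying inside
[0, f_max]: the shoulder flexor alone may carry anything from 0 to its
full 1200 N depending on co-contraction — the spread that single-point
optimization hides.

The `examples/` directory holds one short script per capability
(projection operators, the arm model, muscle-space dynamics, feasible
force sets, the reflex and reaching experiments, reaction envelopes),
each printing the numbers it computes and what they mean.  A thin CLI
(`myospace simulate-reflex | simulate-task | feasible-forces |
sample-polytope | reaction-bounds`) wraps the experiment runners and
writes CSV time series plus a JSON run manifest.

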