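# Methods

This note documents the models, numerical choices and limitations of
`myospace`.  Everything stated here is computed by the test suite or the
acceptance script; nothing is asserted beyond what the code checks.

## Projection algebra

All operators derive from one singular value decomposition per matrix.
Singular values below `rtol · σ_max` (default `rtol = 1e-10`) are
treated as zero; the four projectors `T = A A⁺`, `F = A⁺ A`,
`N_T = I − T`, `N_F = I − F` are built from the retained singular
subspaces (`T = U_r U_rᵀ`, `F = V_r V_rᵀ`), which makes symmetry exact by
construction, idempotence hold to rounding error, and `F + N_F = I`
exact.  Without the explicit cutoff, the defining identities fail
silently near rank deficiency — the reason the bundle stores `rank` and
`rtol` alongside the matrices.  A consistency check
`‖(I − T) b‖ ≤ 1e-8 · (1 + ‖b‖)` guards the solution decomposition: the
theory assumes consistent systems, and violations are reported with the
out-of-range residual rather than silently least-squares'd away.

## The planar arm

An n-joint planar chain with relative revolute angles
(counter-clockwise positive, zero posture = chain extended along +x).
Dynamics come from the Lagrangian, differentiated symbolically and
compiled to one numeric function with a shared subexpression pass, so
`M`, the bias force, moment arms and task Jacobians and their time
derivatives are exact closed forms (finite differences appear only in
tests, as the independent check, and for the null-projector rate below).
The bias convention is `M q̈ + f = τ` with
`f = Ṁ q̇ − ∂T/∂q + ∂V/∂q + c ∘ q̇ − τ_ext`.

Muscles are polylines through points fixed in segment frames; lengths
are Euclidean, and each path edge is evaluated in the frame of its
proximal host segment so the expression involves only the joints the
edge spans.  `R = ∂l_m/∂q` follows symbolically.

### Default geometry (a documented stand-in)

The bundled arm has segment lengths (0.33, 0.31, 0.18) m, masses
(2.0, 1.3, 0.4) kg and rod-like inertias — a 50th-percentile adult arm.
Six mono-articular muscles form antagonist pairs across the three
joints; three bi-articular muscles span shoulder–elbow (both sides) and
elbow–wrist.  The values are the package's own choice: they fix the
numbers the published topology (3 DoFs, 9 muscles, some bi-articular)
leaves open, and every one is overridable through the YAML config.

Two routing details matter and were verified numerically over the whole
reaching workspace (joint box q₁ ∈ [−1.5, 0.9], q₂ ∈ [0.4, 2.2],
q₃ ∈ [0.2, 2.1] rad):

- A *straight-line* muscle's moment arm flips sign once the joint flexes
  far enough that the line crosses the joint center (≈ 0.8 rad for
  near-joint attachments).  The muscle on the habitually stretched side
  of each joint is therefore routed through two via-points close to the
  joint, one per adjacent segment at *unequal* radii — a pulley
  approximation that keeps its moment arm useful to ≈ 2.3 rad of flexion
  without wrapping surfaces (out of scope), and whose unequal radii
  guarantee the inter-via edge can never collapse to zero length.
- With these choices `rank(R) = 3` everywhere in the box and torques of
  ±(5, 5, 3) N·m per joint are realizable within the force bounds
  (checked by linear programming at 400 random postures).

Gravity defaults to zero: the posture and reaching experiments do not
specify a gravity load, and asserting one would change their outcomes.
Passive viscous joint damping (0.4, 0.3, 0.1) N·m·s/rad is part of the
bundled plant: the task-space controller deliberately leaves the
task-null joint motion uncommanded, and a frictionless distal segment
would accumulate null-space velocity until its moment arms degenerate.
Tissue damping is the physically faithful stabilizer and lives in the
plant model, not the controller; it defaults to zero for user-built
models.

The default experiment posture `(−0.327, 1.506, 1.209)` rad places the
hand at ≈ (0.30, 0.30) m, chosen once so that all four cardinal reaching
displacements of 0.3 m stay inside the workspace with `R` full rank
throughout.

## Space projections

`Λ_t = (J_t M⁻¹ J_tᵀ)⁻¹` is inverted directly (d = 2); a condition
number above `1/rtol` raises a kinematic-singularity error — the package
fails loudly at singularities instead of damping, because the theory
assumes full rank and silent regularization would mask property-test
failures.  `Λ_m = (R M⁻¹ Rᵀ)⁺` uses the pseudoinverse since the product
has rank n < m by construction.

The null-projector rate `Ṅ_TR` (needed in the muscle bias when the free
null velocity `l̇_m0` is nonzero) is computed by central differences of
`N_TR` along the trajectory, `N_TR(q ± q̇ δ)` with `δ = 1e-5 s`: the
analytic form involves `d(R⁺)/dt`, which is awkward to state robustly,
while the projector varies smoothly at fixed rank.  With the default
unbiased strategy `l̇_m0 = l̈_m0 = 0` the term vanishes; `l̈_m0` is
exposed only for completeness since `Λ_m N_TR = 0` annihilates it
anyway.

## Feasible force polytope

Bounds `lo ≼ f_m∥ + N_TR f_m0 ≼ hi` are rewritten over an orthonormal
basis `B` of range(`N_TR`) (rank `r = m − n`; `N_TR B = B`), giving
`[B; −B] y ≼ [hi − f_m∥; f_m∥ − lo]` — 2m rows, full column rank, hence
bounded whenever feasible.  Without the reduction the system is
trivially unbounded along the directions `N_TR` annihilates.  For the
linear muscle model `(lo, hi) = (0, f_max)`; the hill-type hook supplies
`(c₀, c₁ + c₀)` from force–length/velocity/passive curves — the bundled
curves are synthetic stand-in shapes (bell / sigmoid / exponential) and
exist to exercise the interface, not to model a particular muscle.

Vertex enumeration has two backends behind one contract: a combinatorial
brute force (solve every r-subset of hyperplanes, keep feasible points —
the reference oracle, cost `C(2m, r)`) and Qhull's halfspace
intersection seeded with the Chebyshev center (production; falls back to
brute force for 1-D or degenerate interiors).  Feasibility and
boundedness are established first by linear programs; infeasible systems
return an empty set flagged infeasible, unbounded ones raise.  Vertices
and samples are deduplicated at absolute tolerance `1e-9` (greedy
pairwise for small sets, grid binning for large ones); the midpoint
sampler would otherwise count coincident midpoints (e.g. the two
diagonals of a square face) multiple times and bias the summary
statistics.

The minimum-norm null correction solves `min ‖y‖²` s.t. `Z y ≼ β` — a
projection of the origin onto the polytope — via SLSQP with analytic
gradients from the Chebyshev center (trivially `y = 0` when feasible).
It is prepended to every feasible force set's samples, so the
minimum-effort solution is always available as sample 0.

Summary statistics are per-muscle min/quartiles/median/max and the
Pearson correlation matrix across samples (Pearson on raw forces is a
choice; a rank correlation would be equally defensible).  Zero-variance
muscles have no defined correlation: those entries are flagged in a
boolean mask and set to 0 instead of propagating NaN.

## Joint reactions

Planar Newton recursion from the distal segment inward, with each
muscle applied as equal-and-opposite tension forces at its attachment
points (each path point is pulled toward its neighbours along the
path).  Envelopes over a feasible force set are component-wise per
joint: the reaction is affine in the muscle forces, so component
extremes over the polytope are attained at the enumerated vertices and
bracket any interior solution — in particular the minimum-norm one.
The magnitude range is also reported; its upper end is sound (convexity
of the norm) but an interior point's magnitude may fall below every
vertex magnitude, which is why containment is asserted on components.

## Controllers and simulation

- Reflex law `l̈_m = k_p (l_md − l_m(t−τ_so)) − k_d l̇_m(t−τ_so)` with
  defaults k_p = k_d = 10, spindle delay τ_so = 20 ms, `l_md` the
  lengths at t = 0.  Muscle forces follow from the muscle-space
  equations with the minimum-norm feasible null correction (the
  quadratic program above), so commanded forces are always
  physiological.
- Task law `ẍ_cmd = ẍ_d + k_p (x_d − x_t) + k_d (ẋ_d − ẋ_t)`
  (k_p = 50, k_d = 5) mapped through `f_t = Λ_t (ẍ_cmd + b_t) + J̄_tᵀ f`
  and `τ = J_tᵀ f_t` with no secondary joint-space objective (τ₀ = 0);
  the torque is realized by bounded muscle forces through the same QP.
- Desired trajectories: `a/2 (tanh(b(t − t₀)) + 1)` displacement along
  +x rotated by γ (a = 0.3 m, b = 4 s⁻¹, t₀ = 1 s): bell-shaped speed,
  peak `a b / 2` at t₀.  Disturbance: Gaussian impulse
  `a exp(−(t−t₀)²/σ²)` (15 N, t₀ = 0.1 s, σ = 0.01 s, −x direction).
- Integration: fixed-step RK4 at dt = 1 ms, controller evaluated once
  per step.  The muscle torque `−Rᵀ f_m` is held over the step
  (zero-order hold at the actuation level).  This matters: holding the
  *forces* and re-evaluating `R` at RK4 stage states leaks
  co-contraction-dependent torque through the within-step change of the
  moment arms and breaks the movement-invisibility of null-space forces;
  holding the torque keeps two runs that differ only in `f_m0` identical
  to ≈ 1e-13 rad.  The fixed step also keeps the delay buffer exact and
  the runs bit-deterministic.
- Delayed feedback: dense per-step history of `(l_m, l̇_m)` with linear
  interpolation; times before the start clamp to the initial state.

Experiment horizons are the package's choice: the reflex return is
simulated for 5 s (the k_p/k_d = 1 s⁻¹ overdamped pole decays with a
~1 s time constant, so ~5 time constants bring the posture error below
0.01 rad), the damping-only variant and each reaching direction for 2 s.

## Problem sizes and fixtures

Property suites run at: 200 random matrices (shapes ≤ 12×8, all rank
patterns) for the projector algebra; 50 random arm states for the
muscle-space inertia identities; 50 random bounded systems (r ≤ 5) for
the enumeration-backend cross-check; 10 movement instants for
feasible-force validity; 6 instants and depth-0 sets for the reaction
envelopes.  Random fixtures (models, polytopes) flow from a single
named seed through one generator — no hidden global state.  Random
polytopes are feasible and bounded by construction (a box containing
the origin plus oblique interior cuts); random models perturb the
default geometry while preserving its antagonist topology.  The 1-DoF
toy (`R = [[1],[1]]`, unit bounds) matches the hand-computed worked
examples.

What the synthetic models do *not* emulate: muscle wrapping over bone,
tendon elasticity, activation dynamics, force–length/velocity curves of
a specific muscle, gravity loading of the experiments, and motor noise.
Tests passing on these models validate the projection algebra, polytope
machinery and control scheme — not the physiological accuracy of any
particular limb.

## Known limitations

- Straight-line/via-point routing only; moment arms of the stand-in
  geometry are plausible in magnitude (2–6 cm) but not anatomical.
- The reaction recursion reports constraint forces of ideal revolute
  joints; no articular contact model.
- The hill-type hook linearizes activation bounds at the current
  kinematic state; it is not a muscle model.
- Vertex enumeration is exact but exponential in principle; the default
  model (r = 6, 18 halfspaces) takes ~0.1 s per instant, and the brute
  force oracle is kept to r ≤ 6.  High-dimensional models need
  randomized samplers, which are out of scope.
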