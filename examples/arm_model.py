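"""The bundled planar arm: 3 joints, 9 muscles, analytic dynamics.

Builds the default model, evaluates the quantities every projection
needs, and verifies one derivative against finite differences.
"""

import numpy as np

import myospace as ms

model = ms.build_planar_arm(ms.default_arm_parameters(),
                            reference_posture=ms.default_initial_posture())
q0 = model.reference_posture
state = ms.ModelState(q=q0, qdot=np.array([0.3, -0.2, 0.5]))

dyn = ms.evaluate_dynamics(model, state)
print("joint-space inertia M(q) [kg m^2]:\n", np.round(dyn.M, 4))
print("bias force f(q, qd) [N m]:", np.round(dyn.f, 4))

mus = ms.evaluate_muscle_kinematics(model, state)
print("\nmoment-arm matrix R (m x n = %d x %d) [m]:" % mus.R.shape)
for name, row in zip(model.muscle_names, mus.R):
    print(f"  {name:14s} {np.round(row, 4)}")
# each row is d(lm_i)/dq: a positive entry means the muscle lengthens as
# that joint flexes, and (negated) how its force maps to joint torque

task = ms.evaluate_task_kinematics(model, state)
print("\nhand position xt [m]:", np.round(task.xt, 4))
print("task Jacobian Jt:\n", np.round(task.Jt, 4))

eps = 1e-6
fd = (model.muscle_lengths(state.q + [eps, 0, 0])
      - model.muscle_lengths(state.q - [eps, 0, 0])) / (2 * eps)
print("\nmax |R[:,0] - finite difference| =",
      float(np.abs(mus.R[:, 0] - fd).max()),
      "(closed-form derivative vs numeric check)")
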