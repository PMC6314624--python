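"""Muscle-space equations of motion and the three routes to a solution.

Projects the dynamics onto muscle space, checks the defining properties
of the muscle-space inertia, and shows that the task, joint and muscle
routes to a particular muscle-force solution agree.
"""

import numpy as np

import myospace as ms

model = ms.build_planar_arm(ms.default_arm_parameters(),
                            reference_posture=ms.default_initial_posture())
state = ms.ModelState(q=model.reference_posture,
                      qdot=np.array([0.4, -0.3, 0.2]))

mp = ms.muscle_projection(model, state)
T_R = mp.R @ mp.R_pinv
print("muscle-space inertia Lambda_m: %d x %d, rank %d"
      % (*mp.Lambda_m.shape, np.linalg.matrix_rank(mp.Lambda_m, tol=1e-8)))
print("|Lambda_m - Lambda_m'|      =", np.abs(mp.Lambda_m - mp.Lambda_m.T).max())
print("|Lambda_m N_TR| (must be 0) =", np.abs(mp.Lambda_m @ mp.N_TR).max())
print("|Lambda_m Lambda_m+ - T_R|  =",
      np.abs(mp.Lambda_m @ np.linalg.pinv(mp.Lambda_m) - T_R).max())
# Lambda_m is the apparent inertia felt in muscle coordinates; it is rank
# n < m, so anything in the moment-arm null space carries no inertia.

# one consistent motion, three coordinate systems
dyn = ms.evaluate_dynamics(model, state)
tk = ms.evaluate_task_kinematics(model, state)
mk = ms.evaluate_muscle_kinematics(model, state)
ft = np.array([2.0, -1.0])                   # desired hand force
tau = tk.Jt.T @ ft
qdd = np.linalg.solve(dyn.M, tau - dyn.f)
xdd = tk.Jtdot @ state.qdot + tk.Jt @ qdd
lmdd = mk.Rdot @ state.qdot + mk.R @ qdd

fm_task = ms.particular_muscle_forces(model, state, "task", xdd)
fm_joint = ms.particular_muscle_forces(model, state, "joint", qdd)
fm_muscle = ms.particular_muscle_forces(model, state, "muscle", lmdd)
print("\nparticular muscle forces (joint route) [N]:", np.round(fm_joint, 3))
print("task-route vs joint-route max diff  :", np.abs(fm_task - fm_joint).max())
print("muscle-route vs joint-route max diff:", np.abs(fm_muscle - fm_joint).max())
# the three lines of the particular-solution formula describe the same
# physics; agreement to rounding error confirms the projections compose.
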