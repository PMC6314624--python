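"""Point-to-point reaching under task-space control.

The hand tracks a smooth sigmoid trajectory (bell-shaped speed profile,
0.3 m displacement along -x) produced by a task-space inverse-dynamics
controller with PD tracking; joint torques are realized by bounded
muscle forces at every step.
"""

import numpy as np

import myospace as ms

model = ms.build_planar_arm(ms.default_arm_parameters(),
                            reference_posture=ms.default_initial_posture())
mm = ms.MuscleModelSpec.linear(model.f_max)
ctrl = ms.TaskController(
    ms.TrajectorySpec(a=0.3, b=4.0, t0=1.0, gamma=np.pi), mm,
    kp=50.0, kd=5.0)
res = ms.simulate(model, ctrl, duration=2.0, dt=1e-3)

xd, _, _ = ctrl.desired(res.time[-1])
print("start hand position : ", np.round(res.xt[0], 4), "m")
print("final hand position : ", np.round(res.xt[-1], 4), "m")
print("target              : ", np.round(xd, 4), "m")
print("terminal task error :  %.2e m" % np.linalg.norm(res.xt[-1] - xd))
speed = np.linalg.norm(np.gradient(res.xt, res.time, axis=0), axis=1)
print("peak hand speed     :  %.3f m/s at t = %.2f s "
      "(theory a*b/2 = %.1f m/s at t0 = 1 s)"
      % (speed.max(), res.time[np.argmax(speed)], 0.3 * 4.0 / 2))
print("muscle force bounds respected:",
      bool(res.fm.min() >= -1e-6 and (res.fm <= model.f_max + 1e-6).all()))
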