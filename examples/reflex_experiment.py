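"""Posture control through spinal-reflex feedback in muscle space.

A Gaussian force impulse hits the hand at t = 0.1 s; delayed muscle
length/velocity feedback (spindle delay 20 ms) drives a muscle-space
inverse-dynamics controller that restores the posture.  Runs ~2.5 s of
simulated time (the full return takes ~5 s; see the reaching example
for the task-space counterpart).
"""

import numpy as np

import myospace as ms

model = ms.build_planar_arm(ms.default_arm_parameters(),
                            reference_posture=ms.default_initial_posture())
mm = ms.MuscleModelSpec.linear(model.f_max)
ctrl = ms.ReflexController(
    ms.ReflexParams(kp=10.0, kd=10.0, tau_so=0.02), mm)
res = ms.simulate(model, ctrl, duration=2.5, dt=1e-3,
                  disturbance=ms.DisturbanceSpec(a=15.0, t0=0.1, sigma=0.01))

dev = np.abs(res.q - res.q[0]).max(axis=1)
print("peak joint deflection   : %.3f rad at t = %.2f s"
      % (dev.max(), res.time[np.argmax(dev)]))
print("posture error at 2.5 s  : %.4f rad (decaying to < 0.01 by ~5 s)"
      % dev[-1])
print("peak muscle force       : %.0f N (bounds 0..f_max respected: %s)"
      % (res.fm.max(), bool(res.fm.min() >= -1e-6
                            and (res.fm <= model.f_max + 1e-6).all())))
# the impulse knocks the arm away; the delayed reflex loop absorbs it
# and pulls every muscle back to its original length, hence the posture
# back to where it started.
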