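"""Task- and muscle-space projections of the equations of motion."""

import numpy as np
import pytest

import myospace as ms
from myospace.linalg import projectors
from conftest import random_state


@pytest.fixture(scope="module")
def square_task_arm():
    """2-joint arm: the planar task Jacobian is square (no kinematic
    redundancy)."""
    from myospace.model import ModelParameters, MusclePath

    mus = (MusclePath("f1", ((0, (-0.06, 0.025)), (1, (0.04, 0.025)))),
           MusclePath("e1", ((0, (-0.06, -0.025)), (1, (0.04, -0.025)))),
           MusclePath("f2", ((1, (0.24, 0.025)), (2, (0.04, 0.025)))),
           MusclePath("e2", ((1, (0.24, -0.025)), (2, (0.04, -0.025)))))
    p = ModelParameters(segment_lengths=(0.3, 0.25),
                        com_distances=(0.15, 0.12), masses=(1.5, 1.0),
                        inertias=(0.012, 0.006), muscles=mus,
                        f_max=(500.0,) * 4)
    return ms.build_planar_arm(p, reference_posture=np.array([0.4, 0.8]))


class TestTaskProjection:
    def test_task_inertia_and_bias_formulas(self, arm):
        rng = np.random.default_rng(0)
        st = random_state(arm, rng, qd_scale=1.0)
        tp = ms.task_projection(arm, st)
        d = ms.evaluate_dynamics(arm, st)
        kin = ms.evaluate_task_kinematics(arm, st)
        Minv = np.linalg.inv(d.M)
        assert np.allclose(tp.Lambda_t,
                           np.linalg.inv(kin.Jt @ Minv @ kin.Jt.T))
        assert np.allclose(tp.b_t, -kin.Jtdot @ st.qdot)
        assert np.allclose(tp.Jbar_T, tp.Lambda_t @ kin.Jt @ Minv)

    def test_dynamically_consistent_inverse_decouples_null_torques(self, arm):
        """Jt M^-1 (I - Jt' Jbar') annihilates any tau0, while the plain
        MPP null projector leaves a substantial residual."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            st = random_state(arm, rng, qd_scale=1.0)
            tp = ms.task_projection(arm, st)
            Minv = np.linalg.inv(tp.M)
            tau0 = rng.normal(size=3)
            good = tp.Jt @ Minv @ (np.eye(3) - tp.Jt.T @ tp.Jbar_T) @ tau0
            assert np.abs(good).max() < 1e-8 * max(1, np.abs(tau0).max())
            mpp = tp.Jt @ Minv @ (np.eye(3)
                                  - tp.Jt.T @ tp.Jt_pinv.T) @ tau0
            assert np.abs(mpp).max() > 1e-4

    def test_square_jacobian_leaves_no_null_space(self, square_task_arm):
        m = square_task_arm
        st = ms.ModelState(q=m.reference_posture, qdot=np.zeros(2))
        tp = ms.task_projection(m, st)
        assert np.abs(tp.N_FJt).max() < 1e-10
        # tau = Jt' ft is exactly invertible
        ft = np.array([3.0, -1.0])
        tau = ms.task_force_map(ft, np.zeros(2), tp)
        assert np.allclose(np.linalg.solve(tp.Jt.T, tau), ft)

    def test_singularity_raises(self, arm):
        st = ms.ModelState(q=np.zeros(3), qdot=np.zeros(3))  # fully extended
        with pytest.raises(ms.KinematicSingularityError):
            ms.task_projection(arm, st)


class TestMuscleProjection:
    def test_proposition1_properties(self, arm):
        """Lambda_m symmetric; invariant under T_R; Lambda_m Lambda_m+ =
        T_R; Lambda_m N_TR = 0."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            st = random_state(arm, rng, qd_scale=1.0)
            mp = ms.muscle_projection(arm, st)
            T_R = mp.R @ mp.R_pinv
            scale = np.abs(mp.Lambda_m).max()
            assert np.abs(mp.Lambda_m - mp.Lambda_m.T).max() < 1e-8 * scale
            assert np.abs(mp.Lambda_m @ T_R - mp.Lambda_m).max() < 1e-8 * scale
            assert np.abs(mp.Lambda_m @ np.linalg.pinv(mp.Lambda_m)
                          - T_R).max() < 1e-8
            assert np.abs(mp.Lambda_m @ mp.N_TR).max() < 1e-8 * scale

    def test_unbiased_strategy_bias_term(self, arm):
        rng = np.random.default_rng(3)
        st = random_state(arm, rng, qd_scale=1.0)
        mp = ms.muscle_projection(arm, st)  # lmdot0 defaults to zero
        assert np.array_equal(mp.b_m, -(mp.Rdot @ st.qdot))

    def test_ntr_dot_matches_projector_differences(self, arm):
        """The finite-difference projector rate integrates consistently:
        N_TR(q + qd h) - N_TR(q) ~ Ndot_TR * h."""
        rng = np.random.default_rng(4)
        st = random_state(arm, rng, qd_scale=1.0)
        mp = ms.muscle_projection(arm, st, lmdot0=np.ones(9))
        h = 1e-4
        N1 = projectors(arm.moment_arm(st.q + st.qdot * h)).N_T
        assert np.abs((N1 - mp.N_TR) / h - mp.Ndot_TR).max() < 1e-2

    def test_lmdot0_dimension_checked(self, pendulum):
        with pytest.raises(ms.InvalidInputError):
            ms.muscle_projection(pendulum,
                                 ms.ModelState(q=[0.3], qdot=[0.0]),
                                 lmdot0=[1.0, 2.0, 3.0])


class TestForceMaps:
    def test_toy_muscle_force_map(self):
        """1-DoF, 2-muscle toy: fm = -R+' tau + N_TR fm0."""
        toy = ms.toy_1dof()
        R = toy["R"]
        b = projectors(R)
        # hand-checked operators
        assert np.allclose(b.pinv, [[0.5, 0.5]])
        assert np.allclose(b.N_T, [[0.5, -0.5], [-0.5, 0.5]])
        fm = -b.pinv.T @ np.array([-1.0])
        assert np.allclose(fm, [0.5, 0.5])
        fm2 = fm + b.N_T @ np.array([1.0, 0.0])
        assert np.allclose(fm2, [1.0, 0.0])
        assert np.allclose(-R.T @ fm2, [-1.0])  # torque unchanged

    def test_round_trip_and_null_annihilation(self, arm):
        rng = np.random.default_rng(5)
        st = random_state(arm, rng)
        tp = ms.task_projection(arm, st)
        mp = ms.muscle_projection(arm, st)
        ft = rng.normal(size=2)
        tau = ms.task_force_map(ft, np.zeros(3), tp)
        assert np.allclose(tp.Jt_pinv.T @ tau, ft, atol=1e-10)
        # pure null torque has no task-force image
        tau_null = ms.task_force_map(np.zeros(2), rng.normal(size=3), tp)
        assert np.abs(tp.Jt_pinv.T @ tau_null).max() < 1e-10
        # muscle null term never changes the torque
        fm = ms.muscle_force_map(tau, rng.normal(size=9), mp)
        assert np.allclose(-mp.R.T @ fm, tau, atol=1e-8)

    def test_null_space_torque_invariance(self, arm):
        """R' N_TR v = 0 for many random v at random states."""
        rng = np.random.default_rng(6)
        for _ in range(10):
            st = random_state(arm, rng)
            mp = ms.muscle_projection(arm, st)
            V = rng.normal(size=(9, 100))
            res = np.abs(mp.R.T @ (mp.N_TR @ V)).max(axis=0)
            assert np.all(res <= 1e-8 * np.linalg.norm(V, axis=0))

    def test_moment_arm_duality(self, arm):
        """Projectors of R and of R+' span the same subspaces."""
        rng = np.random.default_rng(7)
        st = random_state(arm, rng)
        R = arm.moment_arm(st.q)
        bR = projectors(R)
        bRpT = projectors(bR.pinv.T)
        assert np.abs(bR.T - bRpT.T).max() < 1e-10
        assert np.abs(bR.F - bRpT.F).max() < 1e-10


class TestParticularSolutions:
    def test_static_rest_needs_no_force(self, arm):
        st = ms.ModelState(q=arm.reference_posture, qdot=np.zeros(3))
        fm = ms.particular_muscle_forces(arm, st, "joint", np.zeros(3))
        assert np.allclose(fm, 0.0, atol=1e-12)

    def test_joint_and_muscle_routes_agree(self, arm):
        rng = np.random.default_rng(8)
        for _ in range(10):
            st = random_state(arm, rng, qd_scale=1.0)
            qdd = rng.normal(size=3)
            kin = ms.evaluate_muscle_kinematics(arm, st)
            lmdd = kin.Rdot @ st.qdot + kin.R @ qdd  # consistent motion
            fm_j = ms.particular_muscle_forces(arm, st, "joint", qdd)
            fm_m = ms.particular_muscle_forces(arm, st, "muscle", lmdd)
            assert np.abs(fm_j - fm_m).max() < 1e-8 * (1 + np.abs(fm_j).max())

    def test_task_and_joint_routes_agree_for_task_realizable_torque(self, arm):
        rng = np.random.default_rng(9)
        for _ in range(10):
            st = random_state(arm, rng, qd_scale=1.0)
            d = ms.evaluate_dynamics(arm, st)
            kin = ms.evaluate_task_kinematics(arm, st)
            ft = rng.normal(size=2)
            tau = kin.Jt.T @ ft          # no task-null component
            qdd = np.linalg.solve(d.M, tau - d.f)
            xdd = kin.Jtdot @ st.qdot + kin.Jt @ qdd
            fm_t = ms.particular_muscle_forces(arm, st, "task", xdd)
            fm_j = ms.particular_muscle_forces(arm, st, "joint", qdd)
            assert np.abs(fm_t - fm_j).max() < 1e-7 * (1 + np.abs(fm_j).max())
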