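"""Feasible force polytopes: construction, enumeration, sampling, summary."""

import numpy as np
import pytest

import myospace as ms
from myospace.linalg import projectors
from myospace.polytope import (Halfspaces, build_force_inequalities,
                               enumerate_vertices, feasible_force_set,
                               force_space_summary, min_norm_point,
                               sample_polytope)
from conftest import random_state


def cube_system():
    """The printed 6-halfspace worked example: |x_i| <= 0.5 in 3-D."""
    A = np.array([[0, 0, -1], [0, -1, 0], [1, 0, 0],
                  [-1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    return Halfspaces(Z=A, beta=np.full(6, 0.5))


def vertex_sets_equal(V1, V2, tol=1e-8):
    if len(V1) != len(V2):
        return False
    used = set()
    for v in V1:
        hit = [j for j in range(len(V2)) if j not in used
               and np.linalg.norm(v - V2[j], ord=np.inf) <= tol]
        if not hit:
            return False
        used.add(hit[0])
    return True


class TestBuildInequalities:
    def test_toy_reduces_to_interval_of_halfwidth_half(self):
        """2-muscle toy at tau = -1: the feasible null correction is an
        interval of half-width 0.5 along (1,-1)/sqrt(2)."""
        toy = ms.toy_1dof()
        b = projectors(toy["R"])
        fm_par = -b.pinv.T @ np.array([-1.0])      # (0.5, 0.5)
        mm = ms.MuscleModelSpec.linear(toy["f_max"])
        H = build_force_inequalities(fm_par, mm, b.N_T)
        assert H.variable_dim == 1
        assert H.Z.shape == (4, 1)
        vs = enumerate_vertices(H)
        fm_extremes = fm_par[None, :] + vs.vertices @ H.basis.T
        assert vertex_sets_equal(fm_extremes,
                                 np.array([[0.0, 1.0], [1.0, 0.0]]))
        # half-width 0.5 in muscle coordinates
        assert np.isclose(np.abs(fm_extremes - fm_par).max(), 0.5)

    def test_identity_projector_gives_box(self):
        f_max = np.array([2.0, 4.0, 6.0])
        mm = ms.MuscleModelSpec.linear(f_max)
        H = build_force_inequalities(f_max / 2, mm, np.eye(3))
        vs = enumerate_vertices(H)
        expected = np.array([[sx * 1.0, sy * 2.0, sz * 3.0]
                             for sx in (-1, 1) for sy in (-1, 1)
                             for sz in (-1, 1)])
        got = vs.vertices @ H.basis.T
        assert vertex_sets_equal(got, expected)

    def test_default_model_yields_2m_rows(self, arm, linear_muscles):
        st = ms.ModelState(q=arm.reference_posture, qdot=np.zeros(3))
        mp = ms.muscle_projection(arm, st)
        H = build_force_inequalities(np.zeros(9), linear_muscles, mp.N_TR)
        assert H.Z.shape == (18, 6)    # 2m rows, r = m - n columns

    def test_hill_hook_bounds_widen_with_passive_force(self):
        f_max = np.array([100.0, 100.0])
        lm_ref = np.array([0.1, 0.1])
        mm = ms.MuscleModelSpec.hill_hook(f_max, lm_ref)
        lo, hi = mm.bounds(lm=np.array([0.12, 0.1]))   # first muscle stretched
        assert lo[0] > 0 and np.isclose(lo[1], 0.0)
        assert hi[0] > lo[0]
        lin_lo, lin_hi = ms.MuscleModelSpec.linear(f_max).bounds()
        assert np.allclose(lin_lo, 0) and np.allclose(lin_hi, f_max)


class TestVertexEnumeration:
    def test_printed_cube_has_eight_corner_vertices(self):
        vs = enumerate_vertices(cube_system())
        assert len(vs.vertices) == 8
        assert np.allclose(np.abs(vs.vertices), 0.5, atol=1e-9)
        assert np.isclose(np.abs(vs.vertices).max(), 0.5)

    def test_one_dimensional_interval(self):
        H = Halfspaces(Z=np.array([[1.0], [-1.0]]), beta=np.array([2.0, 3.0]))
        vs = enumerate_vertices(H)
        assert vertex_sets_equal(vs.vertices, np.array([[-3.0], [2.0]]))

    def test_backends_match_combinatorial_oracle(self):
        """Qhull and the brute-force oracle return identical vertex sets
        on random bounded systems."""
        for seed in range(20):
            H = ms.random_polytope(seed)
            v_bf = enumerate_vertices(H, backend="bruteforce").vertices
            v_qh = enumerate_vertices(H, backend="qhull").vertices
            assert len(v_bf) > 0
            assert vertex_sets_equal(v_bf, v_qh), f"seed {seed}"

    def test_infeasible_system_flagged_empty(self):
        H = Halfspaces(Z=np.array([[1.0], [-1.0]]),
                       beta=np.array([-2.0, 1.0]))   # x <= -2 and x >= -1
        vs = enumerate_vertices(H)
        assert not vs.feasible
        assert len(vs.vertices) == 0

    def test_unbounded_system_raises(self):
        H = Halfspaces(Z=np.array([[1.0, 0.0], [0.0, 1.0]]),
                       beta=np.array([1.0, 1.0]))     # no lower bounds
        with pytest.raises(ms.UnboundedPolytopeError):
            enumerate_vertices(H)

    def test_rank_deficient_projector_bounded_after_reduction(self, arm):
        """Reducing N_TR to a basis of its range makes the system bounded
        even though N_TR itself is singular."""
        st = ms.ModelState(q=arm.reference_posture, qdot=np.zeros(3))
        mp = ms.muscle_projection(arm, st)
        assert np.linalg.matrix_rank(mp.N_TR, tol=1e-8) == 6  # singular 9x9
        mm = ms.MuscleModelSpec.linear(arm.f_max)
        H = build_force_inequalities(np.zeros(9), mm, mp.N_TR)
        vs = enumerate_vertices(H)     # would raise if unbounded
        assert vs.feasible and len(vs.vertices) >= 7


class TestSampling:
    def test_cube_sampling_counts(self):
        H = cube_system()
        assert len(sample_polytope(H, depth=0)) == 8
        pts = sample_polytope(H, depth=1)
        # 8 vertices + 12 edge midpoints + 6 face centers + 1 body center
        assert len(pts) == 27
        assert np.all(H.contains(pts, tol=1e-12))

    def test_samples_satisfy_inequalities(self):
        for seed in (3, 4):
            H = ms.random_polytope(seed)
            pts = sample_polytope(H, depth=2)
            assert np.all(H.contains(pts, tol=1e-9))

    def test_convex_combinations_stay_feasible(self):
        rng = np.random.default_rng(0)
        H = ms.random_polytope(11)
        pts = sample_polytope(H, depth=1)
        for _ in range(50):
            i, j = rng.integers(0, len(pts), size=2)
            lam = rng.uniform()
            assert H.contains(lam * pts[i] + (1 - lam) * pts[j],
                              tol=1e-12)[0]

    def test_min_norm_point(self):
        H = cube_system()
        assert np.allclose(min_norm_point(H), 0.0)    # origin inside
        # shift the cube so the origin is outside: x in [1, 2]^3
        H2 = Halfspaces(Z=H.Z, beta=np.array([-1, -1, 2, -1, 2, 2.0]))
        assert np.allclose(min_norm_point(H2), [1.0, 1.0, 1.0], atol=1e-6)


class TestFeasibleForceSet:
    def test_zero_action_contains_zero_sample(self, arm, linear_muscles):
        st = ms.ModelState(q=arm.reference_posture, qdot=np.zeros(3))
        fset = feasible_force_set(arm, st, np.zeros(3), linear_muscles)
        assert np.allclose(fset.fm_par, 0.0)
        assert np.any(np.all(np.abs(fset.samples) < 1e-9, axis=1))

    def test_samples_realize_torque_and_respect_bounds(self, arm,
                                                       linear_muscles):
        rng = np.random.default_rng(1)
        st = random_state(arm, rng)
        tau = np.array([2.0, -1.5, 0.5])
        fset = feasible_force_set(arm, st, tau, linear_muscles, depth=1)
        R = arm.moment_arm(st.q)
        assert np.abs(-fset.samples @ R - tau).max() < 1e-8
        assert fset.samples.min() > -1e-7
        assert (fset.samples - arm.f_max).max() < 1e-7

    def test_impossible_action_raises_capacity_error(self, arm,
                                                     linear_muscles):
        st = ms.ModelState(q=arm.reference_posture, qdot=np.zeros(3))
        with pytest.raises(ms.CapacityError):
            feasible_force_set(arm, st, np.array([500.0, 0.0, 0.0]),
                               linear_muscles)


class TestSummary:
    def test_perfect_tradeoff_gives_correlation_minus_one(self):
        fset = ms.FeasibleForceSet(
            fm_par=np.array([0.5, 0.5]),
            samples=np.array([[0.0, 1.0], [0.5, 0.5], [1.0, 0.0]]),
            muscle_model=ms.MuscleModelSpec.linear([1.0, 1.0]),
            state_tag=0.0, muscle_names=("a", "b"))
        s = force_space_summary(fset)
        assert np.isclose(s.correlation[0, 1], -1.0)
        assert not s.undefined.any()
        assert np.allclose(s.stats["min"], [0.0, 0.0])
        assert np.allclose(s.stats["median"], [0.5, 0.5])
        assert np.allclose(s.stats["max"], [1.0, 1.0])

    def test_toy_tradeoff_correlation_from_model(self, pendulum):
        """Muscles sharing one joint trade off along the null direction;
        for the same-signed toy the correlation is -1, for mirrored
        antagonists co-contraction makes it +1."""
        mm = ms.MuscleModelSpec.linear(pendulum.f_max)
        st = ms.ModelState(q=[0.2], qdot=[0.0])
        fset = feasible_force_set(pendulum, st, np.array([1.0]), mm, depth=1)
        s = force_space_summary(fset)
        assert s.correlation[0, 1] > 0.99   # antagonist co-contraction

    def test_degenerate_muscles_flagged_not_nan(self):
        fset = ms.FeasibleForceSet(
            fm_par=np.zeros(2),
            samples=np.array([[1.0, 1.0], [2.0, 1.0], [3.0, 1.0]]),
            muscle_model=ms.MuscleModelSpec.linear([5.0, 5.0]),
            state_tag=0.0, muscle_names=("a", "b"))
        s = force_space_summary(fset)
        assert s.undefined[0, 1] and s.undefined[1, 1]
        assert not np.isnan(s.correlation).any()

    def test_single_sample_rejected(self):
        fset = ms.FeasibleForceSet(
            fm_par=np.zeros(2), samples=np.array([[1.0, 1.0]]),
            muscle_model=ms.MuscleModelSpec.linear([5.0, 5.0]),
            state_tag=0.0)
        with pytest.raises(ms.InvalidInputError):
            force_space_summary(fset)


class TestJointReactions:
    def test_zero_everything_gives_zero_reactions(self, arm):
        q = arm.reference_posture
        F = ms.joint_reaction_forces(arm, q, np.zeros(3), np.zeros(3),
                                     np.zeros(9))
        assert np.allclose(F, 0.0)

    def test_static_pendulum_statics_oracle(self, pendulum_gravity):
        """Closed-form statics: without muscles the joint carries the
        weight; co-contraction strictly increases the reaction."""
        model = pendulum_gravity
        p = model.params
        q = np.array([0.0])
        # hold the horizontal posture: tau = m g Lc
        tau_hold = np.array([p.masses[0] * 9.81 * p.com_distances[0]])
        mm = ms.MuscleModelSpec.linear(model.f_max)
        fset = feasible_force_set(model, ms.ModelState(q=q, qdot=[0.0]),
                                  tau_hold, mm, depth=0)
        mags = [np.linalg.norm(
            ms.joint_reaction_forces(model, q, [0.0], [0.0], fm)[0])
            for fm in fset.samples]
        # min-norm sample leads; the co-contracted vertex reacts harder
        assert max(mags) > mags[0] + 1.0
        # without any muscle force the reaction is exactly the weight
        F0 = ms.joint_reaction_forces(model, q, [0.0], [0.0], np.zeros(2))
        assert np.allclose(F0[0], [0.0, p.masses[0] * 9.81])

    def test_envelope_contains_minimum_norm_solution(self, arm,
                                                     linear_muscles):
        rng = np.random.default_rng(2)
        traj, fsets = [], []
        for k in range(3):
            st = random_state(arm, rng)
            tau = rng.normal(size=3)
            qdd = np.linalg.solve(arm.mass_matrix(st.q),
                                  tau - arm.bias_force(st.q, st.qdot))
            traj.append((0.1 * k, st.q, st.qdot, qdd))
            fsets.append(feasible_force_set(arm, st, tau, linear_muscles))
        env = ms.joint_reaction_bounds(arm, traj, fsets)
        assert env.contains(env.min_norm, tol=1e-6)
        assert np.all(env.mag_hi >= env.mag_lo)
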