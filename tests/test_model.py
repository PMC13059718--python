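"""Core ODE model: derivatives, switch, integration, fixed points, Jacobian."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ferrodyn import (
    ModelParams,
    ModelState,
    death_switch,
    find_fixed_points,
    jacobian,
    rhs,
    simulate,
)


class TestRhs:
    def test_carrying_capacity_with_zero_ros_is_equilibrium(self, canonical):
        dn, dr = rhs(ModelState(n=canonical.K, r=0.0), canonical)
        assert dn == pytest.approx(0.0, abs=1e-15)
        assert dr == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("r", [0.0, 0.5, 3.7])
    def test_extinction_line_is_invariant(self, canonical, r):
        dn, _ = rhs(ModelState(n=0.0, r=r), canonical)
        assert dn == 0.0

    def test_hand_evaluated_derivatives_at_half_confluence(self, canonical):
        # alpha*n*(1-n/K) = 0.05*0.5*0.5 and a*alpha*(1-n/K) = 4*0.05*0.5
        dn, dr = rhs(ModelState(n=0.5, r=0.0), canonical)
        assert dn == pytest.approx(0.0125, rel=1e-12)
        assert dr == pytest.approx(0.1, rel=1e-12)

    def test_rejects_invalid_parameters(self):
        with pytest.raises(ValueError):
            ModelParams(b=0.02, c=0.10)  # ROS would grow without bound
        with pytest.raises(ValueError):
            ModelParams(h=0.5)
        with pytest.raises(ValueError):
            ModelParams(alpha=float("nan"))
        with pytest.raises(ValueError):
            ModelState(n=-0.1, r=0.0)


class TestDeathSwitch:
    def test_zero_ros_means_no_ferroptosis(self, canonical):
        assert death_switch(0.0, canonical) == 0.0

    @pytest.mark.parametrize("h", [1.0, 2.0, 4.0, 8.0])
    def test_half_maximal_exactly_at_threshold(self, canonical, h):
        p = canonical.with_(h=h)
        assert death_switch(p.r0, p) == pytest.approx(0.5, rel=1e-12)

    def test_twice_threshold_steep_hill(self, canonical):
        # r = 2 r0, h = 4: 16 / 17
        assert death_switch(2 * canonical.r0, canonical) == pytest.approx(16 / 17, rel=1e-12)

    def test_monotone_and_saturating(self, canonical):
        r = np.linspace(0, 50, 400)
        s = death_switch(r, canonical)
        assert np.all(np.diff(s) >= 0)
        assert s[-1] > 0.999
        assert np.all((s >= 0) & (s <= 1))

    def test_hard_switch_is_step_at_threshold(self, canonical):
        assert death_switch(canonical.r0 * 0.999, canonical, hard=True) == 0.0
        assert death_switch(canonical.r0 * 1.001, canonical, hard=True) == 1.0

    def test_negative_ros_rejected(self, canonical):
        with pytest.raises(ValueError):
            death_switch(-0.1, canonical)


class TestSimulate:
    def test_matches_closed_form_logistic_without_death_or_ros(self, canonical):
        p = canonical.with_(beta=0.0, a=0.0, c=0.0)
        t = np.linspace(0, 200, 51)
        n0 = 0.05
        traj = simulate(p, ModelState(n=n0, r=0.0), t)
        expected = p.K * n0 * np.exp(p.alpha * t) / (p.K + n0 * (np.exp(p.alpha * t) - 1))
        np.testing.assert_allclose(traj.n, expected, rtol=1e-6)

    def test_matches_closed_form_ros_decay_without_production(self, canonical):
        p = canonical.with_(a=0.0, c=0.0)
        t = np.linspace(0, 100, 41)
        traj = simulate(p, ModelState(n=0.0, r=2.0), t)
        np.testing.assert_allclose(traj.r, 2.0 * np.exp(-p.b * t), rtol=1e-6)

    def test_low_density_converges_to_sensitive_attractor(self, canonical):
        traj = simulate(canonical, ModelState(n=0.10, r=0.0), np.linspace(0, 4000, 101))
        assert traj.final_state.r == pytest.approx(2.0, abs=0.05)
        assert traj.final_state.n == pytest.approx(0.2, abs=0.05)

    def test_deterministic(self, canonical):
        t = np.linspace(0, 100, 21)
        a = simulate(canonical, ModelState(n=0.3, r=0.1), t)
        b = simulate(canonical, ModelState(n=0.3, r=0.1), t)
        np.testing.assert_array_equal(a.n, b.n)
        np.testing.assert_array_equal(a.r, b.r)

    def test_rejects_unsorted_times(self, canonical):
        with pytest.raises(ValueError):
            simulate(canonical, ModelState(n=0.1, r=0.0), [0.0, 2.0, 1.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n0=st.floats(0.0, 1.2),
        r0_init=st.floats(0.0, 4.0),
        seed_t=st.floats(10.0, 500.0),
    )
    def test_states_stay_non_negative(self, n0, r0_init, seed_t):
        p = ModelParams()
        traj = simulate(p, ModelState(n=n0, r=r0_init), np.linspace(0, seed_t, 20))
        assert np.all(traj.n >= -1e-9)
        assert np.all(traj.r >= -1e-9)


class TestFixedPoints:
    def test_canonical_bistability(self, canonical):
        fps = find_fixed_points(canonical)
        stable = [fp for fp in fps if fp.is_stable]
        assert len(stable) == 2
        resistant = max(stable, key=lambda fp: fp.state.n)
        sensitive = min(stable, key=lambda fp: fp.state.n)
        assert resistant.state.n == pytest.approx(canonical.K, abs=1e-8)
        assert resistant.state.r == pytest.approx(0.0, abs=1e-8)
        assert sensitive.state.n == pytest.approx(0.2, abs=0.01)
        assert sensitive.state.r == pytest.approx(2.0, abs=0.01)

    def test_equilibrium_residuals_small(self, canonical):
        for fp in find_fixed_points(canonical):
            dn, dr = rhs(fp.state, canonical)
            assert np.hypot(dn, dr) < 1e-8

    def test_extinction_line_point_matches_closed_form(self, canonical):
        # n = 0 forces r* = a alpha / (b - c)
        expected_r = canonical.a * canonical.alpha / (canonical.b - canonical.c)
        fps = find_fixed_points(canonical)
        on_axis = [fp for fp in fps if fp.state.n == pytest.approx(0.0, abs=1e-8)
                   and fp.state.r > 0.1]
        assert len(on_axis) == 1
        assert on_axis[0].state.r == pytest.approx(expected_r, rel=1e-8)

    def test_no_interior_root_leaves_only_boundary_points(self, canonical):
        # without ROS production the only steady states are (K, 0) and (0, 0)
        p = canonical.with_(a=0.0, c=0.0, beta=0.5)
        fps = find_fixed_points(p)
        coords = sorted((round(fp.state.n, 8), round(fp.state.r, 8)) for fp in fps)
        assert coords == [(0.0, 0.0), (p.K, 0.0)]

    def test_classification_consistent_with_eigenvalues(self, canonical):
        for fp in find_fixed_points(canonical):
            re = [ev.real for ev in fp.eigenvalues]
            if fp.classification == "stable":
                assert max(re) < 0
            elif fp.classification == "unstable":
                assert min(re) > 0
            elif fp.classification == "saddle":
                assert min(re) < 0 < max(re)


class TestJacobian:
    def test_decoupled_limit_has_known_eigenvalues(self, canonical):
        p = canonical.with_(beta=0.0, a=0.0, c=0.0)
        eig = np.linalg.eigvals(jacobian(ModelState(n=p.K, r=0.0), p))
        np.testing.assert_allclose(sorted(eig.real), sorted([-p.alpha, -p.b]), rtol=1e-12)

    def test_resistant_state_locally_stable(self, canonical):
        eig = np.linalg.eigvals(jacobian(ModelState(n=canonical.K, r=0.0), canonical))
        assert np.all(eig.real < 0)

    def test_matches_finite_differences_on_random_states(self, canonical, rng):
        eps = 1e-6
        for _ in range(100):
            n, r = rng.uniform(0.01, 1.2), rng.uniform(0.01, 4.0)
            J = jacobian(ModelState(n=n, r=r), canonical)
            J_num = np.empty((2, 2))
            for j, (dn_, dr_) in enumerate([(eps, 0.0), (0.0, eps)]):
                fp = rhs(ModelState(n=n + dn_, r=r + dr_), canonical)
                fm = rhs(ModelState(n=n - dn_, r=r - dr_), canonical)
                J_num[:, j] = (np.array(fp) - np.array(fm)) / (2 * eps)
            np.testing.assert_allclose(J, J_num, atol=1e-5)
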