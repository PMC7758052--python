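"""Value, complexity, free energy and classical water-maze measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from watermaze import (
    BetaPolicy,
    DiscreteModel,
    TankGeometry,
    Trajectory,
    beta_policy,
    discrete_gain,
    empirical_policy_controls,
    estimate_velocities,
    floating_episodes,
    free_energy,
    performance_measures,
    simulate_ensemble,
    simulate_trajectory,
    solve_dare,
    trajectory_complexity,
    trajectory_cost_value,
)

from conftest import DT


def _traj(positions, dt=DT, velocities=None, **kw):
    return Trajectory(positions=np.asarray(positions, float), dt=dt,
                      velocities=velocities, **kw)


class TestEstimateVelocities:
    def test_uniform_motion_is_exact(self):
        t = np.arange(20) * DT
        v = np.array([3.0, -2.0])
        tr = estimate_velocities(_traj(np.outer(t, [1, 1]) * v))
        assert np.allclose(tr.velocities, v)

    def test_stationary_gives_zero(self):
        tr = estimate_velocities(_traj(np.full((10, 2), 7.0)))
        assert np.allclose(tr.velocities, 0.0)

    def test_sinusoid_taylor_bound(self):
        # central-difference error on interior samples is bounded by the
        # third-derivative Taylor remainder (2 pi f)^3 dt^2 / 6
        f = 0.3
        t = np.arange(200) * DT
        pos = np.column_stack([np.sin(2 * np.pi * f * t), np.zeros_like(t)])
        tr = estimate_velocities(_traj(pos), smooth_window=1)
        true_v = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        err = np.abs(tr.velocities[1:-1, 0] - true_v[1:-1])
        bound = (2 * np.pi * f) ** 3 * DT**2 / 6
        assert err.max() < bound

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            estimate_velocities(_traj([[0, 0], [1, 1]]))


class TestCostValue:
    def test_at_target_with_zero_control_is_zero(self, dmodel, dcost, geometry):
        target = geometry.target_state
        n = 10
        tr = _traj(np.tile(target[:2], (n, 1)), velocities=np.zeros((n, 2)))
        cost, value = trajectory_cost_value(
            tr, dmodel, dcost, np.zeros((n - 1, 2)), target
        )
        assert cost == 0.0 and value == 0.0

    def test_two_step_hand_example(self, dmodel, geometry):
        from watermaze import CostMatrices

        target = np.zeros(4)
        Q = np.diag([2.0, 0.0, 0.0, 0.0])
        dc = CostMatrices(Q=Q, R=np.eye(2), N=np.zeros((4, 2)))
        tr = _traj([[1.0, 0.0], [1.0, 0.0]], velocities=np.zeros((2, 2)))
        cost, value = trajectory_cost_value(tr, dmodel, dc, np.zeros((1, 2)), target)
        assert cost == pytest.approx(1.0)
        assert value == pytest.approx(-1.0)

    def test_optimal_closed_loop_cost_is_machine_zero(self, dmodel, cost, gain, geometry):
        # inverse-optimal weights used as discrete weights: the cost along the
        # noiseless optimal closed loop vanishes identically
        sol = solve_dare(dmodel, cost)
        K = discrete_gain(dmodel, cost, sol).K
        x0 = np.array([*geometry.release_points["E"], 0.0, 0.0])
        traj, controls = simulate_trajectory(
            dmodel, BetaPolicy(beta=1e15, K=K), x0, geometry, noise=False,
            max_steps=300,
        )
        c, v = trajectory_cost_value(traj, dmodel, cost, controls, geometry.target_state)
        assert abs(c) < 1e-10

    def test_misaligned_controls_raise(self, dmodel, dcost, geometry):
        tr = _traj(np.zeros((5, 2)), velocities=np.zeros((5, 2)))
        with pytest.raises(ValueError):
            trajectory_cost_value(tr, dmodel, dcost, np.zeros((5, 2)),
                                  geometry.target_state)


class TestComplexity:
    def test_zero_controls_zero_complexity(self, dmodel):
        assert trajectory_complexity(np.zeros((50, 2)), dmodel) == 0.0

    def test_single_step_hand_example(self):
        B_dt = np.zeros((4, 2))
        B_dt[2, 0] = B_dt[3, 1] = 0.01
        Sigma = np.diag([0.5, 0.5, 0.8, 0.8])
        dm = DiscreteModel(A_dt=np.eye(4), B_dt=B_dt, Sigma_dt=Sigma, dt=DT)
        I = trajectory_complexity(np.array([[10.0, 0.0]]), dm)
        assert I == pytest.approx(0.5 * 0.1**2 / 0.8)

    def test_matches_monte_carlo_kl(self, dmodel):
        # per-step KL between controlled and free transition laws, estimated
        # by importance-free Monte Carlo with 1e6 draws
        u = np.array([3.0, -2.0])
        I_formula = trajectory_complexity(u[None, :], dmodel)
        rng = np.random.default_rng(0)
        L = dmodel.noise_chol
        n = 10**6
        x = rng.standard_normal((n, 4)) @ L.T + dmodel.B_dt @ u
        Sinv = np.linalg.inv(dmodel.Sigma_dt)
        d1 = x - dmodel.B_dt @ u
        lr = 0.5 * (
            np.einsum("ti,ij,tj->t", x, Sinv, x)
            - np.einsum("ti,ij,tj->t", d1, Sinv, d1)
        )
        se = lr.std(ddof=1) / np.sqrt(n)
        assert abs(lr.mean() - I_formula) < 3 * se

    def test_rotation_invariance(self, dmodel):
        # isotropic noise: rotating the control frame leaves complexity fixed
        rng = np.random.default_rng(1)
        u = rng.standard_normal((40, 2))
        theta = 0.7
        Rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        assert trajectory_complexity(u, dmodel) == pytest.approx(
            trajectory_complexity(u @ Rot.T, dmodel), rel=1e-12
        )

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        ux=st.floats(-30, 30), uy=st.floats(-30, 30),
        scale=st.floats(0.1, 10), theta=st.floats(0, 2 * np.pi),
    )
    def test_quadratic_scaling_and_rotation_invariance(
        self, dmodel, ux, uy, scale, theta
    ):
        # the per-step KL is a quadratic form in the control, invariant to
        # rigid rotation of the (isotropic) coordinate frame
        u = np.array([[ux, uy]])
        base = trajectory_complexity(u, dmodel)
        assert base >= 0.0
        assert trajectory_complexity(scale * u, dmodel) == pytest.approx(
            scale**2 * base, rel=1e-9, abs=1e-12
        )
        Rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        assert trajectory_complexity(u @ Rot.T, dmodel) == pytest.approx(
            base, rel=1e-9, abs=1e-12
        )

    def test_additivity_in_steps(self, dmodel):
        u = np.array([[1.0, 2.0], [3.0, -1.0]])
        total = trajectory_complexity(u, dmodel)
        assert total == pytest.approx(
            trajectory_complexity(u[:1], dmodel) + trajectory_complexity(u[1:], dmodel)
        )


class TestPolicyControls:
    def test_naive_policy_gives_zero_controls(self, dmodel, dcost, geometry):
        pol = beta_policy(dmodel, dcost, 0.0)
        tr = _traj(np.random.default_rng(0).uniform(-40, 40, (20, 2)),
                   velocities=np.zeros((20, 2)))
        u = empirical_policy_controls(tr, pol, geometry.target_state)
        assert np.all(u == 0.0)
        assert trajectory_complexity(u, dmodel) == 0.0

    def test_zero_error_gives_zero_control(self, dmodel, dcost, geometry):
        pol = beta_policy(dmodel, dcost, 10.0)
        target = geometry.target_state
        tr = _traj(np.tile(target[:2], (5, 1)), velocities=np.zeros((5, 2)))
        assert np.allclose(empirical_policy_controls(tr, pol, target), 0.0)

    def test_linearity_in_state_error(self, dmodel, dcost, geometry):
        pol = beta_policy(dmodel, dcost, 10.0)
        target = geometry.target_state
        e = np.array([10.0, -4.0, 2.0, 1.0])
        tr1 = _traj((target[:2] + e[:2])[None].repeat(3, 0),
                    velocities=(target[2:] + e[2:])[None].repeat(3, 0))
        tr2 = _traj((target[:2] + 2 * e[:2])[None].repeat(3, 0),
                    velocities=(target[2:] + 2 * e[2:])[None].repeat(3, 0))
        u1 = empirical_policy_controls(tr1, pol, target)
        u2 = empirical_policy_controls(tr2, pol, target)
        assert np.allclose(u2, 2 * u1)


class TestPerformanceMeasures:
    def test_straight_run_to_platform(self, geometry):
        # 50 cm straight approach at 25 cm/s
        start = geometry.platform_center + np.array([50.0, 0.0])
        n = 11  # 2 s at dt=0.2
        pos = start + np.outer(np.linspace(0, 1, n), [-50.0, 0.0])
        tr = _traj(pos)
        latency, path_length, mean_speed, _ = performance_measures(tr, geometry)
        assert path_length == pytest.approx(50.0)
        assert mean_speed == pytest.approx(25.0)
        assert latency <= 2.0

    def test_stationary_gallagher(self, geometry):
        d = 31.0
        pos = geometry.platform_center + np.array([d, 0.0])
        tr = _traj(np.tile(pos, (8, 1)))
        latency, path_length, _, gallagher = performance_measures(tr, geometry)
        assert gallagher == pytest.approx(d)
        assert path_length == 0.0
        assert latency == tr.duration

    def test_circular_arc_speed(self, geometry):
        omega = 0.43
        t = np.arange(100) * DT
        pos = 60.0 * np.column_stack([np.cos(omega * t), np.sin(omega * t)])
        tr = _traj(pos)
        _, _, mean_speed, _ = performance_measures(tr, geometry)
        # chord-vs-arc discretization error bound
        assert abs(mean_speed - 60.0 * omega) <= 0.5 * 60.0 * omega**2 * DT


class TestFloatingEpisodes:
    @staticmethod
    def _with_speeds(speeds):
        n = len(speeds)
        v = np.column_stack([speeds, np.zeros(n)])
        return _traj(np.zeros((n, 2)), velocities=v)

    def test_constant_speed_no_episodes(self):
        n, spans = floating_episodes(self._with_speeds([10.0] * 20))
        assert n == 0 and spans == []

    def test_hand_example_single_episode(self):
        n, spans = floating_episodes(self._with_speeds([10, 10, 0.5, 10, 10]))
        assert n == 1
        assert spans == [(2, 3)]

    def test_two_separated_stops(self):
        n, spans = floating_episodes(
            self._with_speeds([10, 0.1, 10, 10, 0.1, 0.1, 10])
        )
        assert n == 2
        assert spans == [(1, 2), (4, 6)]

    def test_requires_velocities(self):
        with pytest.raises(ValueError):
            floating_episodes(_traj(np.zeros((5, 2))))


class TestFreeEnergy:
    def test_arithmetic(self):
        assert free_energy(0.0, 0.0, 5.0) == 0.0
        assert free_energy(-2.0, 1.0, 3.0) == pytest.approx(7.0)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            free_energy(0.0, 0.0, -1.0)

    def test_affine_in_beta_with_slope_minus_value(self):
        value, complexity = -3.5, 1.2
        betas = np.linspace(0, 10, 7)
        F = np.array([free_energy(value, complexity, b) for b in betas])
        slopes = np.diff(F) / np.diff(betas)
        assert np.allclose(slopes, -value)

    def test_beta_optimal_policy_minimizes_mean_free_energy(
        self, dmodel, dcost, geometry
    ):
        # among the naive policy, the LQR, and perturbed gains, the
        # beta-optimal controller attains the smallest simulated mean F;
        # the optimality statement is for a fixed horizon, and common noise
        # streams remove most of the Monte-Carlo variance between policies
        beta = 3e-4  # inside the value-complexity trade-off region
        pol = beta_policy(dmodel, dcost, beta)
        x0 = np.array([*geometry.release_points["E"], 0.0, 0.0])

        def mean_F(K):
            vals, infos = simulate_ensemble(
                dmodel, dcost, K, x0, geometry, n_reps=300, seed=7,
                seed_key=(0,), max_steps=200, stop_at_platform=False,
            )
            F = infos - beta * vals
            return F.mean(), F.std(ddof=1) / np.sqrt(len(F))

        F_opt, se_opt = mean_F(pol.K)
        K_lqr = beta_policy(dmodel, dcost, 1e15).K
        others = [mean_F(np.zeros((2, 4))), mean_F(K_lqr)]
        rng = np.random.default_rng(11)
        for _ in range(20):
            others.append(mean_F(pol.K * rng.uniform(0.3, 2.5)))
        for F_other, se_other in others:
            assert F_opt <= F_other + 3 * np.hypot(se_opt, se_other)
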