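"""Solver tests: oracle equivalence, bounds, noise handling, emergence."""

import dataclasses

import numpy as np
import pytest

from ofcarm import (CostSpec, SolverOptions, Trajectory,
                    analytic_problem, evaluate_cost, feedback_policy,
                    ilqg_solve, learned_problem, linearize,
                    seed_stream, simulate_trial)
from ofcarm.solver import ControlProblem, QuadraticCost


def lq_system():
    Ac = np.array([[0.0, 1.0], [-0.8, -0.5]])
    Bc = np.array([[0.2, 0.0], [0.5, -0.4]])

    def dyn(X, U):
        X = np.asarray(X, float)
        U = np.asarray(U, float)
        return np.einsum("ij,...j->...i", Ac, X) + np.einsum("ij,...j->...i", Bc, U)

    return Ac, Bc, dyn


def finite_horizon_lqr(Ad, Bd, Q, R, Qf, K):
    """Independent Riccati-recursion oracle (direct dynamic programming)."""
    S = Qf.copy()
    gains = []
    for _ in range(K):
        H = R + Bd.T @ S @ Bd
        L = -np.linalg.solve(H, Bd.T @ S @ Ad)
        gains.append(L)
        Acl = Ad + Bd @ L
        S = Q + L.T @ R @ L + Acl.T @ S @ Acl
    return gains[::-1]


class TestOracles:
    def test_lqr_equivalence(self):
        """On a linear-quadratic problem without bounds or noise, open-loop
        controls and gains match the discrete Riccati solution to 1e-6."""
        Ac, Bc, dyn = lq_system()
        dt, K = 0.1, 20
        problem = ControlProblem(dyn, None, np.array([1.0, -0.5]), dt,
                                 n_controls=2, bounds=None)
        Q, R, Qf = np.diag([1.0, 0.5]), np.diag([0.1, 0.2]), np.diag([50.0, 10.0])
        cost = QuadraticCost(Q, R, Qf)
        sol = ilqg_solve(problem, cost, u_init=np.zeros((K, 2)),
                         options=SolverOptions(max_iter=50))
        Ad, Bd = np.eye(2) + dt * Ac, dt * Bc
        gains = finite_horizon_lqr(Ad, Bd, Q, R, Qf, K)
        x = problem.x0.copy()
        U_opt = []
        for k in range(K):
            u = gains[k] @ x
            U_opt.append(u)
            x = Ad @ x + Bd @ u
        assert np.abs(sol.nominal_controls - np.array(U_opt)).max() < 1e-6
        assert np.abs(sol.gains - np.array(gains)).max() < 1e-6
        assert sol.converged

    def test_modified_riccati_with_control_noise(self):
        """Scalar system with control-multiplicative noise: gains match the
        noise-damped Riccati closed form to 1e-3."""
        a, b, sig, K = 0.95, 0.4, 0.6, 15
        q, r, qf = 1.0, 0.5, 5.0

        def dyn(X, U):
            X = np.asarray(X, float)
            U = np.asarray(U, float)
            return ((a - 1.0) * X[..., 0] + b * U[..., 0])[..., None]

        def noise(X, U):
            U = np.asarray(U, float)
            return (sig * U[..., 0])[..., None, None]

        problem = ControlProblem(dyn, noise, np.array([1.0]), 1.0,
                                 n_controls=1, bounds=None)
        cost = QuadraticCost([[q]], [[r]], [[qf]])
        sol = ilqg_solve(problem, cost, u_init=np.zeros((K, 1)),
                         options=SolverOptions(max_iter=100))
        S = qf
        gains = []
        for _ in range(K):
            H = r + b * b * S + sig * sig * S
            gains.append(-a * b * S / H)
            S = q + a * a * S - (a * b * S) ** 2 / H
        oracle = np.array(gains[::-1])[:, None, None]
        assert np.abs(sol.gains - oracle).max() < 1e-3


class TestCostAndLinearize:
    def test_evaluate_cost_examples(self, params):
        spec = CostSpec(K=3, dt=0.01, q_target=0.3)
        states = np.array([[0.0, 0.0], [0.1, 1.0], [0.2, 0.5], [0.3, 0.0]])
        controls = np.array([[0.2, 0.1], [0.4, 0.0], [0.1, 0.1]])
        accs = np.zeros(3)
        traj = Trajectory(states, controls, accs, 0.01)
        expected = spec.w_e * 0.01 * float(np.sum(controls ** 2))
        assert evaluate_cost(traj, spec) == pytest.approx(expected)
        # ending at rest on target with zero controls costs nothing
        quiet = Trajectory(np.tile([0.3, 0.0], (4, 1)), np.zeros((3, 2)),
                           accs, 0.01)
        assert evaluate_cost(quiet, spec) == 0.0
        # quadratic energy: doubling all controls quadruples the energy term
        double = Trajectory(states, 2 * controls, accs, 0.01)
        assert evaluate_cost(double, spec) == pytest.approx(4 * expected)

    def test_linearize_exact_on_linear_dynamics(self):
        Ac, Bc, dyn = lq_system()
        dt = 0.05
        problem = ControlProblem(dyn, None, np.zeros(2), dt, n_controls=2)
        X = np.array([[0.3, -0.2], [0.1, 0.4]])
        U = np.array([[0.5, 0.2]])
        A, B, *_ = linearize(problem, X, U)
        assert np.allclose(A[0], np.eye(2) + dt * Ac, atol=1e-8)
        assert np.allclose(B[0], dt * Bc, atol=1e-8)

    def test_linearize_against_fine_difference_oracle(self, params,
                                                      extended_noise):
        """Arm Jacobians agree with an independent ultra-fine-step central
        difference to 1e-4 relative."""
        problem = analytic_problem(params, extended_noise)
        X = np.array([[0.2, 0.5], [0.2, 0.5]])
        U = np.array([[0.4, 0.25]])
        A, B, G, Gx, Gu = linearize(problem, X, U, fd_step=1e-4)

        def fd(fn, x, u, h=1e-7):
            n, m = x.size, u.size
            Jx = np.zeros((2, n))
            Ju = np.zeros((2, m))
            for i in range(n):
                e = np.zeros(n); e[i] = h
                Jx[:, i] = (fn(x + e, u) - fn(x - e, u)) / (2 * h)
            for j in range(m):
                e = np.zeros(m); e[j] = h
                Ju[:, j] = (fn(x, u + e) - fn(x, u - e)) / (2 * h)
            return Jx, Ju

        f = lambda x, u: np.asarray(problem.mean_dynamics(x, u), float)
        Jx, Ju = fd(f, X[0], U[0])
        assert np.allclose(A[0], np.eye(2) + problem.dt * Jx, rtol=1e-4, atol=1e-6)
        assert np.allclose(B[0], problem.dt * Ju, rtol=1e-4, atol=1e-6)

    def test_antagonist_signs_in_control_jacobian(self, params):
        """At equilibrium the two muscles accelerate the joint in opposite
        directions."""
        problem = analytic_problem(params, None)
        X = np.array([[0.0, 0.0], [0.0, 0.0]])
        U = np.array([[0.3, 0.3]])
        _, B, *_ = linearize(problem, X, U)
        assert B[0][1, 0] > 0 > B[0][1, 1]


class TestArmSolutions:
    def test_cost_monotonicity_of_accepted_iterates(self, pretrained_extended,
                                                    config):
        problem = learned_problem(pretrained_extended, config.arm.dt)
        sol = ilqg_solve(problem, config.cost, options=dataclasses.replace(
            config.solver, max_iter=25))
        assert len(sol.cost_pairs) > 0
        for before, after in sol.cost_pairs:
            assert after <= before

    def test_bounds_respected(self, pretrained_extended, config):
        problem = learned_problem(pretrained_extended, config.arm.dt)
        sol = ilqg_solve(problem, config.cost, options=dataclasses.replace(
            config.solver, max_iter=25))
        assert np.all(sol.nominal_controls >= 0.0)
        assert np.all(sol.nominal_controls <= 1.0)

    def test_nominal_consistent_with_mean_dynamics(self, pretrained_extended,
                                                   config):
        """The nominal trajectory is the deterministic rollout of the nominal
        controls under the internal model."""
        problem = learned_problem(pretrained_extended, config.arm.dt)
        sol = ilqg_solve(problem, config.cost, options=dataclasses.replace(
            config.solver, max_iter=25))
        x = problem.x0.copy()
        for k in range(sol.nominal_controls.shape[0]):
            f = np.asarray(problem.mean_dynamics(x, sol.nominal_controls[k]),
                           float).reshape(2)
            x = x + problem.dt * f
            assert np.allclose(x, sol.nominal_states[k + 1], atol=1e-9)

    def test_deterministic_variant_abolishes_cocontraction(
            self, pretrained_extended, config):
        """Zeroing the noise map reproduces a deterministic iLQR whose
        co-contraction is a negligible fraction of the stochastic one's."""
        from ofcarm.experiments import _solve
        stoch = _solve(pretrained_extended, config, config.cost)
        det = _solve(pretrained_extended, config, config.cost,
                     deterministic=True)
        cc = lambda s: float(np.sum(np.min(s.nominal_controls, axis=1)) * config.arm.dt)
        assert cc(stoch) > 0.01
        assert cc(det) < 0.05 * cc(stoch)

    def test_cocontraction_concentrates_late(self, pretrained_extended,
                                             config):
        """Impedance is raised near the end of the movement, where noise can
        no longer be corrected."""
        from ofcarm.experiments import _solve
        sol = _solve(pretrained_extended, config, config.cost)
        U = sol.nominal_controls
        quarter = U.shape[0] // 4
        first = np.sum(np.min(U[:quarter], axis=1))
        last = np.sum(np.min(U[-quarter:], axis=1))
        assert last >= first


class TestFeedbackPolicy:
    def test_on_nominal_returns_nominal(self, pretrained_extended, config):
        problem = learned_problem(pretrained_extended, config.arm.dt)
        sol = ilqg_solve(problem, config.cost, options=dataclasses.replace(
            config.solver, max_iter=15))
        policy = feedback_policy(sol)
        for k in (0, 10, 49):
            u = policy(k, sol.nominal_states[k])
            assert np.allclose(u, np.clip(sol.nominal_controls[k], 0, 1))

    def test_saturation(self, pretrained_extended, config):
        problem = learned_problem(pretrained_extended, config.arm.dt)
        sol = ilqg_solve(problem, config.cost, options=dataclasses.replace(
            config.solver, max_iter=15))
        u = policy_out = feedback_policy(sol)(25, np.array([100.0, -100.0]))
        assert np.all(u >= 0.0) and np.all(u <= 1.0)

    def test_feedback_beats_open_loop(self, pretrained_extended, config):
        """Closed-loop reaches have lower endpoint scatter than open-loop
        replays of the same nominal controls."""
        problem = learned_problem(pretrained_extended, config.arm.dt)
        sol = ilqg_solve(problem, config.cost, options=dataclasses.replace(
            config.solver, max_iter=25))
        policy = feedback_policy(sol)
        open_loop = lambda k, x: sol.nominal_controls[k]
        finals = {}
        for name, pol in (("closed", policy), ("open", open_loop)):
            rng = seed_stream(21, "loop", name)
            ends = [simulate_trial(pol, (0.0, 0.0), 50, config.arm,
                                   config.noise, rng).states[-1, 0]
                    for _ in range(100)]
            finals[name] = np.var(ends)
        assert finals["closed"] < finals["open"]
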