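"""Stochastic iterative-LQG trajectory optimization with control bounds.

Solves finite-horizon optimal control for the (learned or analytic) arm
dynamics ``x_{k+1} = x_k + dt f(x_k, u_k) + sum_j g_j(x_k, u_k) xi_jk`` with
``xi ~ N(0, 1)`` per step and channel.  The backward pass carries the
control-dependent-noise correction terms — quadratic forms of each noise
column's control derivative with the cost-to-go curvature — so the optimizer
minimizes the *expected* cost.  That correction is what lets spending energy
on antagonist co-activation pay off: wherever the learned uncertainty drops
with co-contraction faster than the energy term grows, the solution
co-contracts.

Bounds are handled by an exact active-set box-QP for the feedforward step
plus clipping in the rollout (feedback rows are kept even for clamped
controls: a saturated command can still move inward).  A Levenberg-Marquardt
term on the control curvature guards the Newton steps; candidates are
accepted when they improve the expected cost under the backward pass's own
quadratic cost-to-go model.  Two further devices make the nonconvex
expected-cost landscape tractable: the noise columns are ramped up in
continuation stages (warm-started), and the iterate finally returned is the
accepted candidate with the lowest fixed-seed Monte-Carlo expected cost
under the problem's own stochastic model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np

from .config import CostSpec, SolverOptions
from .plant import Trajectory

__all__ = [
    "ControlProblem",
    "ILQGSolution",
    "ReachingCost",
    "QuadraticCost",
    "evaluate_cost",
    "linearize",
    "ilqg_solve",
    "feedback_policy",
]


@dataclass
class ControlProblem:
    """Discrete-time stochastic control problem.

    ``mean_dynamics(X, U)`` maps batched states (..., n) and controls (..., m)
    to state derivatives (..., n); the solver discretizes by explicit Euler at
    ``dt``.  ``noise_map(X, U)``, if given, returns the *discrete* noise
    columns (..., n, J), i.e. already carrying their sqrt(dt)/dt scaling, so
    that ``x' = x + dt f + G @ xi``.  ``bounds`` is (lo, hi) per control or
    None for unconstrained problems.
    """

    mean_dynamics: Callable[[np.ndarray, np.ndarray], np.ndarray]
    noise_map: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]]
    x0: np.ndarray
    dt: float
    n_controls: int = 2
    bounds: Optional[Tuple[np.ndarray, np.ndarray]] = None

    def __post_init__(self) -> None:
        self.x0 = np.asarray(self.x0, dtype=float)
        if self.bounds is not None:
            lo, hi = self.bounds
            self.bounds = (np.broadcast_to(np.asarray(lo, float), (self.n_controls,)).copy(),
                           np.broadcast_to(np.asarray(hi, float), (self.n_controls,)).copy())


@dataclass
class ILQGSolution:
    """Optimizer output: nominal plan, time-varying feedback law, diagnostics."""

    nominal_states: np.ndarray    # (K+1, n)
    nominal_controls: np.ndarray  # (K, m)
    gains: np.ndarray             # (K, m, n)
    expected_cost: float
    iterations: int
    converged: bool
    # per accepted iteration: (cost before, cost after) under that
    # iteration's quadratic cost-to-go model — after <= before always
    cost_pairs: List[Tuple[float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Cost models
# ---------------------------------------------------------------------------

class ReachingCost:
    """Quadratic reaching cost on the (q, qdot) arm state (see CostSpec)."""

    def __init__(self, spec: CostSpec):
        self.spec = spec.validate()

    def running(self, k: int, x: np.ndarray, u: np.ndarray):
        w = self.spec.w_e * self.spec.dt
        l = w * float(u @ u)
        lx = np.zeros_like(x)
        lu = 2.0 * w * u
        lxx = np.zeros((x.size, x.size))
        luu = 2.0 * w * np.eye(u.size)
        lux = np.zeros((u.size, x.size))
        return l, lx, lu, lxx, luu, lux

    def final(self, x: np.ndarray):
        dq = x[0] - self.spec.q_target
        l = self.spec.w_p * dq ** 2 + self.spec.w_v * x[1] ** 2
        lx = np.array([2.0 * self.spec.w_p * dq, 2.0 * self.spec.w_v * x[1]])
        lxx = np.diag([2.0 * self.spec.w_p, 2.0 * self.spec.w_v])
        return l, lx, lxx

    def trajectory_cost(self, X: np.ndarray, U: np.ndarray) -> float:
        dq = X[-1, 0] - self.spec.q_target
        energy = self.spec.w_e * self.spec.dt * float(np.sum(U * U))
        return float(self.spec.w_p * dq ** 2 + self.spec.w_v * X[-1, 1] ** 2 + energy)

    def batch_running(self, k: int, X: np.ndarray, U: np.ndarray) -> np.ndarray:
        return self.spec.w_e * self.spec.dt * np.einsum("mj,mj->m", U, U)

    def batch_final(self, X: np.ndarray) -> np.ndarray:
        dq = X[:, 0] - self.spec.q_target
        return self.spec.w_p * dq ** 2 + self.spec.w_v * X[:, 1] ** 2


class QuadraticCost:
    """Generic LQ cost ½xᵀQx + ½uᵀRu running, ½xᵀQf x final (about x_ref)."""

    def __init__(self, Q: np.ndarray, R: np.ndarray, Qf: np.ndarray,
                 x_ref: Optional[np.ndarray] = None):
        self.Q, self.R, self.Qf = (np.asarray(a, float) for a in (Q, R, Qf))
        self.x_ref = np.zeros(self.Q.shape[0]) if x_ref is None else np.asarray(x_ref, float)

    def running(self, k: int, x: np.ndarray, u: np.ndarray):
        dx = x - self.x_ref
        l = 0.5 * float(dx @ self.Q @ dx + u @ self.R @ u)
        return (l, self.Q @ dx, self.R @ u, self.Q.copy(), self.R.copy(),
                np.zeros((u.size, x.size)))

    def final(self, x: np.ndarray):
        dx = x - self.x_ref
        return 0.5 * float(dx @ self.Qf @ dx), self.Qf @ dx, self.Qf.copy()

    def trajectory_cost(self, X: np.ndarray, U: np.ndarray) -> float:
        total = self.final(X[-1])[0]
        for k in range(U.shape[0]):
            total += self.running(k, X[k], U[k])[0]
        return float(total)

    def batch_running(self, k: int, X: np.ndarray, U: np.ndarray) -> np.ndarray:
        dX = X - self.x_ref
        return 0.5 * (np.einsum("mi,ij,mj->m", dX, self.Q, dX)
                      + np.einsum("mi,ij,mj->m", U, self.R, U))

    def batch_final(self, X: np.ndarray) -> np.ndarray:
        dX = X - self.x_ref
        return 0.5 * np.einsum("mi,ij,mj->m", dX, self.Qf, dX)


def _as_cost(cost):
    return ReachingCost(cost) if isinstance(cost, CostSpec) else cost


def evaluate_cost(traj: Trajectory, cost: CostSpec) -> float:
    """Reaching cost of a realized trajectory (the paper-form performance
    index: final position error, final velocity, integrated squared commands)."""
    cost.validate()
    if traj.K != cost.K:
        raise ValueError(f"trajectory has {traj.K} steps, cost expects {cost.K}")
    return ReachingCost(cost).trajectory_cost(traj.states, traj.controls)


# ---------------------------------------------------------------------------
# Linearization
# ---------------------------------------------------------------------------

def linearize(
    problem: ControlProblem,
    X: np.ndarray,
    U: np.ndarray,
    fd_step: float = 1.0e-4,
):
    """Central finite-difference Jacobians of the discrete dynamics and of
    every noise column along a nominal trajectory.

    Returns ``(A, B, G, Gx, Gu)`` with shapes (K,n,n), (K,n,m), (K,n,J),
    (K,J,n,n), (K,J,n,m); ``G`` and its derivatives are None when the problem
    has no noise map.  All dynamics evaluations are batched into a single
    call so learned-model queries stay vectorized.
    """
    X = np.asarray(X, float)
    U = np.asarray(U, float)
    K, m = U.shape
    n = X.shape[1]
    h = fd_step
    P = 1 + 2 * (n + m)
    Xp = np.repeat(X[:K, None, :], P, axis=1)
    Up = np.repeat(U[:, None, :], P, axis=1)
    col = 1
    for i in range(n):
        Xp[:, col, i] += h
        Xp[:, col + 1, i] -= h
        col += 2
    for j in range(m):
        Up[:, col, j] += h
        Up[:, col + 1, j] -= h
        col += 2

    f = np.asarray(problem.mean_dynamics(Xp, Up), float)     # (K, P, n)
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite dynamics derivative")
    A = np.repeat(np.eye(n)[None], K, axis=0)
    B = np.zeros((K, n, m))
    col = 1
    for i in range(n):
        A[:, :, i] += problem.dt * (f[:, col] - f[:, col + 1]) / (2 * h)
        col += 2
    for j in range(m):
        B[:, :, j] = problem.dt * (f[:, col] - f[:, col + 1]) / (2 * h)
        col += 2

    if problem.noise_map is None:
        return A, B, None, None, None

    g = np.asarray(problem.noise_map(Xp, Up), float)         # (K, P, n, J)
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite noise-column derivative")
    J = g.shape[-1]
    G = np.moveaxis(g[:, 0], -1, 1)                          # (K, J, n)
    Gx = np.zeros((K, J, n, n))
    Gu = np.zeros((K, J, n, m))
    col = 1
    for i in range(n):
        Gx[:, :, :, i] = np.moveaxis((g[:, col] - g[:, col + 1]) / (2 * h), -1, 1)
        col += 2
    for j in range(m):
        Gu[:, :, :, j] = np.moveaxis((g[:, col] - g[:, col + 1]) / (2 * h), -1, 1)
        col += 2
    return A, B, G, Gx, Gu


# ---------------------------------------------------------------------------
# Box-constrained quadratic subproblem (small m: exact active-set enumeration)
# ---------------------------------------------------------------------------

def _box_qp(H: np.ndarray, grad: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """argmin ½ dᵀHd + gradᵀd subject to lo <= d <= hi.

    Enumerates the 3^m active sets (free / at lower / at upper), returning the
    first KKT-consistent candidate; falls back to the best feasible clipped
    candidate.  Also returns the free-dimension mask for gain computation.
    """
    m = grad.size
    # common case: the Newton step is strictly interior
    try:
        d0 = -np.linalg.solve(H, grad)
    except np.linalg.LinAlgError:
        d0 = None
    if d0 is not None and np.all(d0 >= lo) and np.all(d0 <= hi):
        return d0, np.ones(m, dtype=bool)
    best_d, best_free, best_val = None, None, np.inf
    for combo in itertools.product((0, 1, 2), repeat=m):
        d = np.zeros(m)
        free = np.array([c == 0 for c in combo])
        d[np.array(combo) == 1] = lo[np.array(combo) == 1]
        d[np.array(combo) == 2] = hi[np.array(combo) == 2]
        if free.any():
            rhs = -(grad[free] + H[np.ix_(free, ~free)] @ d[~free])
            try:
                d[free] = np.linalg.solve(H[np.ix_(free, free)], rhs)
            except np.linalg.LinAlgError:
                continue
        if np.any(d < lo - 1e-12) or np.any(d > hi + 1e-12):
            continue
        g_at = grad + H @ d
        ok = True
        for i, c in enumerate(combo):
            if c == 0 and not (lo[i] - 1e-9 <= d[i] <= hi[i] + 1e-9):
                ok = False
            if c == 1 and g_at[i] < -1e-9:
                ok = False
            if c == 2 and g_at[i] > 1e-9:
                ok = False
        val = 0.5 * d @ H @ d + grad @ d
        if ok:
            return np.clip(d, lo, hi), free
        if val < best_val:
            best_d, best_free, best_val = np.clip(d, lo, hi), free, val
    return best_d, best_free


# ---------------------------------------------------------------------------
# Backward pass
# ---------------------------------------------------------------------------

def _backward_pass(cost, X, U, A, B, G, Gx, Gu, reg, bounds):
    K, m = U.shape
    n = X.shape[1]
    l_f, lx_f, lxx_f = cost.final(X[K])
    S = lxx_f.astype(float)
    s = lx_f.astype(float)
    S_seq = np.empty((K + 1, n, n))
    S_seq[K] = S
    k_ff = np.empty((K, m))
    gains = np.zeros((K, m, n))
    for k in range(K - 1, -1, -1):
        _, lx, lu, lxx, luu, lux = cost.running(k, X[k], U[k])
        Ak, Bk = A[k], B[k]
        Qx = lx + Ak.T @ s
        Qu = lu + Bk.T @ s
        Qxx = lxx + Ak.T @ S @ Ak
        Quu = luu + Bk.T @ S @ Bk
        Qux = lux + Bk.T @ S @ Ak
        if G is not None:
            for j in range(G.shape[1]):
                gj, Cx, Cu = G[k, j], Gx[k, j], Gu[k, j]
                Sg = S @ gj
                Qx = Qx + Cx.T @ Sg
                Qu = Qu + Cu.T @ Sg
                Qxx = Qxx + Cx.T @ S @ Cx
                Quu = Quu + Cu.T @ S @ Cu
                Qux = Qux + Cu.T @ S @ Cx
        H = 0.5 * (Quu + Quu.T) + reg * np.eye(m)
        try:
            np.linalg.cholesky(H)
        except np.linalg.LinAlgError:
            return None  # caller escalates regularization
        if bounds is not None:
            lo = bounds[0] - U[k]
            hi = bounds[1] - U[k]
            d, _ = _box_qp(H, Qu, lo, hi)
            k_ff[k] = d
            # feedback rows are kept even for clamped dims: the executed
            # policy clips, and a saturated command can still move inward
            L = -np.linalg.solve(H, Qux)
        else:
            d = -np.linalg.solve(H, Qu)
            k_ff[k] = d
            L = -np.linalg.solve(H, Qux)
        gains[k] = L
        S = Qxx + L.T @ H @ L + L.T @ Qux + Qux.T @ L
        S = 0.5 * (S + S.T)
        s = Qx + L.T @ H @ d + L.T @ Qu + Qux.T @ d
        S_seq[k] = S
    return k_ff, gains, S_seq


# ---------------------------------------------------------------------------
# Rollouts and expected cost
# ---------------------------------------------------------------------------

def _rollout(problem, cost, X_ref, U_ref, k_ff, gains, alpha):
    K, m = U_ref.shape
    n = X_ref.shape[1]
    X = np.empty((K + 1, n))
    U = np.empty((K, m))
    X[0] = problem.x0
    for k in range(K):
        u = U_ref[k] + alpha * k_ff[k] + gains[k] @ (X[k] - X_ref[k])
        if problem.bounds is not None:
            u = np.clip(u, problem.bounds[0], problem.bounds[1])
        U[k] = u
        X[k + 1] = X[k] + problem.dt * np.asarray(
            problem.mean_dynamics(X[k], u), float).reshape(n)
    if not np.all(np.isfinite(X)):
        return None, None
    return X, U


def _model_expected_cost(problem, cost, X, U, S_seq):
    """Deterministic trajectory cost + ½ Σ_k Σ_j g_jᵀ S_{k+1} g_j.

    The noise term prices process noise through the current backward pass's
    quadratic cost-to-go; it is the line-search objective (both candidate and
    incumbent are measured under the same S, so every acceptance certifies a
    non-increase of the modeled expected cost)."""
    total = cost.trajectory_cost(X, U)
    if problem.noise_map is None:
        return total
    g = np.asarray(problem.noise_map(X[:-1], U), float)      # (K, n, J)
    return total + 0.5 * float(np.einsum("knj,knm,kmj->", g, S_seq[1:], g))


def _mc_expected_cost(problem, cost, X, U, gains, n_rollouts=64, seed=0x5EED):
    """Monte-Carlo expected cost of the policy (X̄, Ū, L) under the model.

    Simulates the closed-loop policy on the problem's own stochastic model
    (mean dynamics + noise columns), with command clipping, so saturation and
    the control-dependence of the noise along realized deviations are priced
    exactly rather than through a local quadratic model.  A fixed internal
    seed makes the estimate a deterministic functional of the policy — it is
    the arbiter that decides which accepted iterate the solver returns.
    """
    if problem.noise_map is None:
        return cost.trajectory_cost(X, U)
    rng = np.random.default_rng(seed)
    K, m = U.shape
    n = X.shape[1]
    x = np.broadcast_to(problem.x0, (n_rollouts, n)).copy()
    total = np.zeros(n_rollouts)
    for k in range(K):
        u = U[k] + (x - X[k]) @ gains[k].T
        if problem.bounds is not None:
            u = np.clip(u, problem.bounds[0], problem.bounds[1])
        total += _batch_running_cost(cost, k, x, u)
        f = np.asarray(problem.mean_dynamics(x, u), float)
        G = np.asarray(problem.noise_map(x, u), float)        # (n_mc, n, J)
        xi = rng.standard_normal((n_rollouts, G.shape[-1]))
        x = x + problem.dt * f + np.einsum("mnj,mj->mn", G, xi)
    total += _batch_final_cost(cost, x)
    return float(total.mean())


def _batch_running_cost(cost, k, X, U):
    if hasattr(cost, "batch_running"):
        return cost.batch_running(k, X, U)
    return np.array([cost.running(k, x, u)[0] for x, u in zip(X, U)])


def _batch_final_cost(cost, X):
    if hasattr(cost, "batch_final"):
        return cost.batch_final(X)
    return np.array([cost.final(x)[0] for x in X])


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def ilqg_solve(
    problem: ControlProblem,
    cost,
    u_init: Optional[np.ndarray] = None,
    options: Optional[SolverOptions] = None,
    K: Optional[int] = None,
) -> ILQGSolution:
    """Iterate rollout / backward Riccati-like pass / line search to a local
    optimum of the expected cost.

    ``cost`` is a :class:`~ofcarm.config.CostSpec` or any object exposing
    ``running``/``final``/``trajectory_cost``.  ``u_init`` defaults to a small
    symmetric activation per step (K then must be given via the cost spec or
    the ``K`` argument).
    """
    opts = (options or SolverOptions()).validate()
    cost_model = _as_cost(cost)
    if u_init is None:
        steps = K if K is not None else getattr(cost_model, "spec").K
        u_init = np.full((steps, problem.n_controls), 0.01)
    U = np.asarray(u_init, dtype=float).copy()
    if problem.bounds is not None:
        U = np.clip(U, problem.bounds[0], problem.bounds[1])

    # continuation on the noise scale: ramp the noise columns up in stages,
    # warm-starting each, so the impedance component of the solution deforms
    # smoothly from the deterministic reach instead of depending on the
    # exploration luck of a single cold solve
    stages = max(1, int(opts.noise_stages)) if problem.noise_map is not None else 1
    total_iterations = 0
    sol = None
    for stage in range(stages):
        gamma = (stage + 1) / stages
        if gamma == 1.0:
            prob_stage = problem
        else:
            nm = problem.noise_map
            prob_stage = ControlProblem(
                problem.mean_dynamics,
                lambda X, U_, g=gamma, f=nm: g * f(X, U_),
                problem.x0, problem.dt, problem.n_controls, problem.bounds)
        sol = _solve_stage(prob_stage, cost_model, U, opts)
        U = sol.nominal_controls
        total_iterations += sol.iterations
    sol.iterations = total_iterations
    return sol


def _solve_stage(problem, cost_model, u_init, opts) -> ILQGSolution:
    U = np.asarray(u_init, dtype=float).copy()
    steps, m = U.shape
    zeros_k = np.zeros((steps, m))
    zeros_L = np.zeros((steps, m, problem.x0.size))
    X, U = _rollout(problem, cost_model, np.repeat(problem.x0[None], steps + 1, 0),
                    U, zeros_k, zeros_L, 1.0)
    if X is None:
        raise FloatingPointError("initial rollout diverged")

    reg = opts.reg_init
    gains = zeros_L.copy()
    cost_pairs: List[Tuple[float, float]] = []
    converged = False
    iteration = 0
    lin = linearize(problem, X, U, opts.fd_step)
    j_best = _mc_expected_cost(problem, cost_model, X, U, gains)
    best = (X, U, gains, j_best)
    while iteration < opts.max_iter:
        iteration += 1
        back = _backward_pass(cost_model, X, U, *lin, reg, problem.bounds)
        if back is None:
            reg = max(reg, opts.reg_floor) * opts.reg_grow
            if reg > opts.reg_max:
                break
            continue
        k_ff, gains_new, S_seq = back
        j_prev = _model_expected_cost(problem, cost_model, X, U, S_seq)
        accepted = False
        alpha = 1.0
        for _ in range(opts.line_search_steps):
            X_new, U_new = _rollout(problem, cost_model, X, U, k_ff, gains_new, alpha)
            if X_new is not None:
                j_new = _model_expected_cost(problem, cost_model, X_new, U_new, S_seq)
                if j_new < j_prev:
                    accepted = True
                    break
            alpha *= opts.line_search_decay
        if not accepted:
            reg = max(reg, opts.reg_floor) * opts.reg_grow
            if reg > opts.reg_max:
                break
            continue
        cost_pairs.append((j_prev, j_new))
        X, U, gains = X_new, U_new, gains_new
        # closed-loop model evaluation decides which accepted iterate the
        # solver ultimately returns
        lin = linearize(problem, X, U, opts.fd_step)
        j_mc = _mc_expected_cost(problem, cost_model, X, U, gains)
        if j_mc < best[3]:
            best = (X, U, gains, j_mc)
        reg *= opts.reg_shrink
        if reg < opts.reg_floor:
            reg = 0.0 if opts.reg_init == 0.0 else opts.reg_floor
        if alpha == 1.0 and abs(j_prev - j_new) <= opts.tol * max(1.0, abs(j_prev)):
            converged = True
            break

    X, U, gains, j_best = best
    return ILQGSolution(
        nominal_states=X,
        nominal_controls=U,
        gains=gains,
        expected_cost=float(j_best),
        iterations=iteration,
        converged=converged,
        cost_pairs=cost_pairs,
    )


def feedback_policy(sol: ILQGSolution, bounds: Tuple[float, float] = (0.0, 1.0)):
    """Time-varying affine feedback law u(k, x) = clip(ū_k + L_k (x - x̄_k))."""
    lo, hi = bounds

    def policy(k: int, x: np.ndarray) -> np.ndarray:
        u = sol.nominal_controls[k] + sol.gains[k] @ (
            np.asarray(x, float) - sol.nominal_states[k])
        return np.clip(u, lo, hi)

    return policy
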