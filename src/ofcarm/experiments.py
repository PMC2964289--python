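"""End-to-end experiment protocols: pre-train, optimize, simulate, measure.

Four experiment classes drive the emergent impedance-control phenomena:

* ``run_sdn_comparison`` — reaches optimized against forward models learned
  from a standard-SDN vs an extended-SDN plant (co-contraction emerges only
  in the latter);
* ``run_accuracy_sweep`` — five accuracy-demand conditions with scaled final
  cost weights (impedance grows with accuracy demand);
* ``run_velocity_sweep`` — three reach distances at fixed horizon (impedance
  grows with peak speed);
* ``run_adaptation`` — null-field trials followed by force-field trials with
  per-trial re-optimization and online model updates (impedance transients
  track the model's prediction uncertainty).

Every driver is a pure function of (config, seed): all randomness flows
through named child streams of the single seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import learner as learner_mod
from . import plant, solver
from .config import (AdaptationSchedule, CostSpec, ExperimentConfig,
                     NoiseModel, seed_stream)
from .learner import LearnedDynamics

__all__ = [
    "TrialMetrics",
    "compute_trial_metrics",
    "analytic_problem",
    "learned_problem",
    "pretrain_dynamics",
    "run_trials",
    "run_sdn_comparison",
    "run_accuracy_sweep",
    "run_velocity_sweep",
    "run_adaptation",
    "compare_pre_post_adaptation",
]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class TrialMetrics:
    """Per-trial summary statistics used across all experiment figures."""

    endpoint_error: float          # |q_T - q_target|, rad
    endpoint_speed: float          # |qdot_T|, rad/s
    peak_speed: float              # max |qdot|, rad/s
    cocontraction_integral: float  # sum min(u) dt, activation*s
    muscle_integral: float         # sum (u_f + u_e) dt
    flexor_integral: float
    extensor_integral: float
    uncertainty_integral: float    # sum predicted variance dt, (rad/s^2)^2 s
    final_q: float
    limit_hits: int

    def to_dict(self) -> dict:
        return asdict(self)


def compute_trial_metrics(
    traj: plant.Trajectory,
    cost: CostSpec,
    model: Optional[LearnedDynamics] = None,
) -> TrialMetrics:
    """Measure a realized trajectory.

    The uncertainty integral evaluates the *current* learned model's
    predictive variance along the trajectory's (state, control) points, so
    after a force-field trial it reflects the freshly updated model.
    """
    u = traj.controls
    dt = traj.dt
    uncertainty = 0.0
    if model is not None:
        Z = np.concatenate([traj.states[:-1], u], axis=1)
        _, var, _ = model.predict(Z)
        uncertainty = float(np.sum(var) * dt)
    return TrialMetrics(
        endpoint_error=float(abs(traj.states[-1, 0] - cost.q_target)),
        endpoint_speed=float(abs(traj.states[-1, 1])),
        peak_speed=float(np.max(np.abs(traj.states[:, 1]))),
        cocontraction_integral=float(np.sum(np.min(u, axis=1)) * dt),
        muscle_integral=float(np.sum(u) * dt),
        flexor_integral=float(np.sum(u[:, 0]) * dt),
        extensor_integral=float(np.sum(u[:, 1]) * dt),
        uncertainty_integral=uncertainty,
        final_q=float(traj.states[-1, 0]),
        limit_hits=int(traj.limit_hits),
    )


# ---------------------------------------------------------------------------
# Control problems over analytic or learned dynamics
# ---------------------------------------------------------------------------

def analytic_problem(
    params,
    noise: Optional[NoiseModel],
    x0=(0.0, 0.0),
    external_fx: float = 0.0,
) -> solver.ControlProblem:
    """Arm control problem with the closed-form plant as internal model.

    The discrete noise columns carry the Euler-Maruyama scaling: each muscle
    channel contributes sqrt(dt) * a_i * sigma_i(u) / M to the velocity row.
    """
    params.validate()

    def dynamics(X, U):
        X = np.asarray(X, float)
        acc = plant.forward_dynamics(X, U, params, external_fx)
        return np.stack([X[..., 1], acc], axis=-1)

    noise_map = None
    if noise is not None and noise.kind != "none":
        a_f, a_e = params.moment_arms
        scale = np.array([a_f, -a_e]) * np.sqrt(params.dt) / params.inertia

        def noise_map(X, U):
            sigma = plant.tension_noise_std(np.asarray(U, float), noise)
            G = np.zeros(sigma.shape[:-1] + (2, 2))
            G[..., 1, :] = sigma * scale
            return G

    return solver.ControlProblem(dynamics, noise_map, np.asarray(x0, float),
                                 params.dt, n_controls=2,
                                 bounds=(np.zeros(2), np.ones(2)))


def learned_problem(
    model: LearnedDynamics,
    dt: float,
    x0=(0.0, 0.0),
    deterministic: bool = False,
) -> solver.ControlProblem:
    """Arm control problem whose internal model is the learned dynamics.

    The single noise column is dt * predictive-std on the velocity row (the
    learner's variance is that of the realized per-step acceleration, which
    already contains the 1/sqrt(dt) diffusion factor).  ``deterministic=True``
    zeroes the noise map: the optimizer ignores the uncertainty information.
    """
    mean = model.mean_fn()
    std = model.std_fn()

    def dynamics(X, U):
        X = np.asarray(X, float)
        return np.stack([X[..., 1], mean(X, U)], axis=-1)

    noise_map = None
    if not deterministic:
        def noise_map(X, U):
            s = std(np.asarray(X, float), np.asarray(U, float))
            G = np.zeros(s.shape + (2, 1))
            G[..., 1, 0] = dt * s
            return G

    return solver.ControlProblem(dynamics, noise_map, np.asarray(x0, float),
                                 dt, n_controls=2,
                                 bounds=(np.zeros(2), np.ones(2)))


# ---------------------------------------------------------------------------
# Pre-training and closed-loop trial batteries
# ---------------------------------------------------------------------------

def pretrain_dynamics(
    config: ExperimentConfig,
    kind: str,
    seed: int,
) -> LearnedDynamics:
    """Motor-babble the plant with the given SDN kind and train a fresh model."""
    noise = replace(config.noise, kind=kind).validate()
    rng = seed_stream(seed, "babble", kind)
    Z, Y = learner_mod.generate_babble_data(config.arm, noise, config.babble, rng)
    model = learner_mod.create_learner(config.learner)
    model.update_batch(Z, Y)
    return model


def run_trials(
    sol: solver.ILQGSolution,
    config: ExperimentConfig,
    noise: NoiseModel,
    cost: CostSpec,
    n_trials: int,
    rng: np.random.Generator,
    model: Optional[LearnedDynamics] = None,
    external_fx: float = 0.0,
    x0=(0.0, 0.0),
) -> pd.DataFrame:
    """Run closed-loop stochastic reaches under the optimized feedback law."""
    policy = solver.feedback_policy(sol)
    rows = []
    for trial in range(n_trials):
        traj = plant.simulate_trial(policy, x0, cost.K, config.arm, noise,
                                    rng, external_fx)
        row = compute_trial_metrics(traj, cost, model).to_dict()
        row["trial"] = trial
        rows.append(row)
    return pd.DataFrame(rows)


def _solve(model, config, cost, u_init=None, options=None, x0=(0.0, 0.0),
           deterministic=False):
    """Plan a reach on the learned model.

    Cold solves are multi-started: once from the small symmetric default and
    once from an end-of-movement co-contraction ramp, keeping whichever
    policy has the lower Monte-Carlo expected cost under the model.  The
    expected-cost landscape is bistable (impedance vs. pure reciprocal
    strategies), and a single start can land in either basin.
    """
    problem = learned_problem(model, config.arm.dt, x0=x0,
                              deterministic=deterministic)
    opts = options or config.solver
    if u_init is not None:
        return solver.ilqg_solve(problem, cost, u_init=u_init, options=opts)
    starts = [np.full((cost.K, 2), 0.01)]
    if not deterministic:
        ramp = 0.01 + 0.5 * (np.arange(cost.K) / cost.K) ** 2
        starts.append(np.repeat(ramp[:, None], 2, axis=1))
    sols = [solver.ilqg_solve(problem, cost, u_init=s, options=opts)
            for s in starts]
    return min(sols, key=lambda s: s.expected_cost)


def run_sdn_comparison(
    config: ExperimentConfig,
    seed: int,
    learners: Optional[Dict[str, LearnedDynamics]] = None,
) -> dict:
    """Standard vs extended SDN: one solve + stochastic trials per condition."""
    config.validate()
    out: dict = {"metrics": {}, "solutions": {}}
    for kind in ("standard", "extended"):
        model = (learners or {}).get(kind) or pretrain_dynamics(config, kind, seed)
        noise = replace(config.noise, kind=kind).validate()
        sol = _solve(model, config, config.cost)
        if not sol.converged and not sol.cost_pairs:
            raise RuntimeError(f"ILQG failed to make progress ({kind} condition)")
        rng = seed_stream(seed, "sdn-trials", kind)
        df = run_trials(sol, config, noise, config.cost, config.n_trials_sdn,
                        rng, model=model)
        df["condition"] = kind
        out["metrics"][kind] = df
        out["solutions"][kind] = sol
    return out


def run_accuracy_sweep(
    config: ExperimentConfig,
    seed: int,
    model: Optional[LearnedDynamics] = None,
) -> dict:
    """Accuracy conditions A..E: final weights scaled about the baseline."""
    config.validate()
    model = model or pretrain_dynamics(config, "extended", seed)
    noise = replace(config.noise, kind="extended").validate()
    labels = [chr(ord("A") + i) for i in range(len(config.accuracy_scales))]
    out: dict = {"metrics": {}, "solutions": {}, "weights": {}}
    for label, scale in zip(labels, config.accuracy_scales):
        cost = replace(config.cost, w_p=config.cost.w_p * scale,
                       w_v=config.cost.w_v * scale)
        sol = _solve(model, config, cost)
        rng = seed_stream(seed, "accuracy-trials", label)
        df = run_trials(sol, config, noise, cost, config.n_trials_condition,
                        rng, model=model)
        df["condition"] = label
        out["metrics"][label] = df
        out["solutions"][label] = sol
        out["weights"][label] = {"w_p": cost.w_p, "w_v": cost.w_v, "w_e": cost.w_e}
    return out


def run_velocity_sweep(
    config: ExperimentConfig,
    seed: int,
    model: Optional[LearnedDynamics] = None,
) -> dict:
    """Near/medium/far targets at fixed horizon and fixed cost weights."""
    config.validate()
    model = model or pretrain_dynamics(config, "extended", seed)
    noise = replace(config.noise, kind="extended").validate()
    labels = ["near", "medium", "far"][: len(config.velocity_targets)]
    out: dict = {"metrics": {}, "solutions": {}}
    for label, target in zip(labels, config.velocity_targets):
        cost = replace(config.cost, q_target=float(target))
        sol = _solve(model, config, cost)
        rng = seed_stream(seed, "velocity-trials", label)
        df = run_trials(sol, config, noise, cost, config.n_trials_condition,
                        rng, model=model)
        df["condition"] = label
        out["metrics"][label] = df
        out["solutions"][label] = sol
    return out


# ---------------------------------------------------------------------------
# Adaptation
# ---------------------------------------------------------------------------

def run_adaptation(
    config: ExperimentConfig,
    seed: int,
    variant: str = "stochastic",
    model: Optional[LearnedDynamics] = None,
    schedule: Optional[AdaptationSchedule] = None,
    replan_max_iter: int = 40,
) -> pd.DataFrame:
    """Null-field then force-field reaching with online model adaptation.

    Per replication the pre-trained model is cloned; before every trial the
    controller re-plans with the current model (warm-started from the
    previous solution), the trial runs on the stochastic plant (force field
    active from trial ``n_nullfield_trials + 1``), the model absorbs the
    trial's samples, and metrics — including the prediction-uncertainty
    integral under the *updated* model — are recorded.

    ``variant='deterministic'`` zeroes the solver's noise map only; plant
    noise and learning are unchanged.
    """
    config.validate()
    if variant not in ("stochastic", "deterministic"):
        raise ValueError(f"unknown variant {variant!r}")
    sched = (schedule or config.adaptation).validate()
    model = model or pretrain_dynamics(config, "extended", seed)
    noise = replace(config.noise, kind="extended").validate()
    cost = replace(config.cost, q_target=sched.q_target,
                   w_p=sched.w_p, w_v=sched.w_v)
    deterministic = variant == "deterministic"

    replan_opts = replace(config.solver, max_iter=replan_max_iter, tol=1e-5,
                          noise_stages=1)

    def solve(mdl, u_init, options):
        return _solve(mdl, config, cost, u_init=u_init, options=options,
                      deterministic=deterministic)

    def replan(mdl, prev):
        """Warm re-plan, guarded: keep the previous policy if the new plan
        does not improve the model's expected cost."""
        if deterministic:
            # deterministic solves are cheap and converge crisply: re-plan
            # cold so stale reciprocal overlap is not carried across trials
            return solve(mdl, None, config.solver)
        sol = solve(mdl, prev.nominal_controls, replan_opts)
        problem = learned_problem(mdl, config.arm.dt)
        cm = solver.ReachingCost(cost)
        j_prev = solver._mc_expected_cost(problem, cm, prev.nominal_states,
                                          prev.nominal_controls, prev.gains)
        return sol if sol.expected_cost <= j_prev else prev

    baseline = solve(model, None, config.solver)
    n_trials = sched.n_nullfield_trials + sched.n_forcefield_trials
    rows: List[dict] = []
    for rep in range(sched.replications):
        mdl = model.copy()
        prev = baseline
        for t in range(1, n_trials + 1):
            if t == 1:
                sol = baseline
            else:
                sol = replan(mdl, prev)
            fx = sched.ff_force if t > sched.n_nullfield_trials else 0.0
            rng = seed_stream(seed, "adapt", variant, f"rep{rep}", f"trial{t}")
            traj = plant.simulate_trial(solver.feedback_policy(sol),
                                        (0.0, 0.0), cost.K, config.arm,
                                        noise, rng, external_fx=fx)
            Z = np.concatenate([traj.states[:-1], traj.controls], axis=1)
            mdl.update_batch(Z, traj.accelerations, passes=sched.replay_passes)
            row = compute_trial_metrics(traj, cost, mdl).to_dict()
            row.update(rep=rep, trial=t,
                       phase="NF" if fx == 0.0 else "FF", variant=variant)
            rows.append(row)
            prev = sol
    return pd.DataFrame(rows)


def compare_pre_post_adaptation(records: pd.DataFrame) -> dict:
    """NF baseline vs late-FF (last five trials) muscle use and kinematics."""
    nf = records[records["phase"] == "NF"]
    last = sorted(records["trial"].unique())[-5:]
    late = records[records["trial"].isin(last)]
    cols = ["flexor_integral", "extensor_integral", "endpoint_error",
            "endpoint_speed", "cocontraction_integral"]
    return {
        "nf": {c: float(nf[c].mean()) for c in cols},
        "late_ff": {c: float(late[c].mean()) for c in cols},
    }
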