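"""Antagonistic single-joint arm: ground-truth plant and data source.

The elbow is a rigid link of inertia ``M`` actuated by a flexor/extensor pair
of linear spring-damper muscles with constant moment arms ``A = (a_f, -a_e)``.
Muscle lengths are affine in the joint angle, ``l = l_ref - A q``, tensions
follow ``t_i = max(0, k(u_i)(l_i - l_rest,i(u_i)) + b(u_i) l̇_i)`` and the
joint torque is ``a_f t_f - a_e t_e``.  Signal-dependent noise enters as a
Gaussian perturbation of the muscle tensions whose standard deviation is a
function of the commands (see :class:`~ofcarm.config.NoiseModel`); the state
is advanced by explicit Euler-Maruyama at the configured step.

All kernels accept scalars or broadcastable arrays; the trailing axis of
2-vector quantities indexes (flexor, extensor).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
import pandas as pd

from .config import ArmParameters, NoiseModel

__all__ = [
    "Trajectory",
    "SimulationDiverged",
    "signed_moment_arms",
    "muscle_geometry",
    "muscle_tension",
    "joint_torque",
    "tension_noise_std",
    "forward_dynamics",
    "acceleration_noise_std",
    "step_stochastic",
    "external_force_torque",
    "simulate_trial",
    "rollout_controls",
    "joint_stiffness",
]


class SimulationDiverged(RuntimeError):
    """The closed-loop state became non-finite (numerical blow-up)."""


@dataclass
class Trajectory:
    """A realized rollout: K+1 states, K controls, K realized accelerations.

    ``accelerations[k]`` is the noise-inclusive joint acceleration that
    advanced step k (the quantity the dynamics learner trains on).
    """

    states: np.ndarray        # (K+1, 2) columns (q, qdot)
    controls: np.ndarray      # (K, 2)   columns (u_flexor, u_extensor)
    accelerations: np.ndarray  # (K,)    rad/s^2, realized
    dt: float
    limit_hits: int = 0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        self.controls = np.asarray(self.controls, dtype=float)
        self.accelerations = np.asarray(self.accelerations, dtype=float)
        K = self.controls.shape[0]
        if self.states.shape != (K + 1, 2) or self.accelerations.shape != (K,):
            raise ValueError("inconsistent trajectory array lengths")

    @property
    def K(self) -> int:
        return self.controls.shape[0]

    def to_frame(self) -> pd.DataFrame:
        k = np.arange(self.K)
        return pd.DataFrame({
            "k": k,
            "t": k * self.dt,
            "q": self.states[:-1, 0],
            "qdot": self.states[:-1, 1],
            "u_flexor": self.controls[:, 0],
            "u_extensor": self.controls[:, 1],
            "qddot_realized": self.accelerations,
        })


def signed_moment_arms(params: ArmParameters) -> np.ndarray:
    """A = (a_f, -a_e): flexor shortens, extensor lengthens as q increases."""
    a_f, a_e = params.moment_arms
    return np.array([a_f, -a_e])


def muscle_geometry(q, qdot, params: ArmParameters) -> Tuple[np.ndarray, np.ndarray]:
    """Muscle lengths and length velocities from the affine joint mapping."""
    A = signed_moment_arms(params)
    ref = np.asarray(params.ref_lengths, dtype=float)
    q = np.asarray(q, dtype=float)[..., None]
    qdot = np.asarray(qdot, dtype=float)[..., None]
    lengths = ref - A * q
    velocities = -A * qdot
    return lengths, np.broadcast_to(velocities, lengths.shape).copy()


def muscle_tension(u, lengths, length_velocities, params: ArmParameters) -> np.ndarray:
    """Spring-damper tensions, clipped at zero (muscles only pull)."""
    u = np.asarray(u, dtype=float)
    k = params.k0 + params.k1 * u
    b = params.b0 + params.b1 * u
    l_rest = np.asarray(params.ref_lengths, dtype=float) - params.r * u
    t = k * (np.asarray(lengths, dtype=float) - l_rest) + b * np.asarray(length_velocities, dtype=float)
    return np.maximum(t, 0.0)


def joint_torque(tensions, params: ArmParameters):
    """Net joint torque a_f t_f - a_e t_e (flexion positive)."""
    a_f, a_e = params.moment_arms
    tensions = np.asarray(tensions, dtype=float)
    return a_f * tensions[..., 0] - a_e * tensions[..., 1]


def tension_noise_std(u, model: NoiseModel) -> np.ndarray:
    """Per-muscle tension-noise standard deviation sigma(u), in newtons."""
    u = np.asarray(u, dtype=float)
    uf, ue = u[..., 0], u[..., 1]
    if model.kind == "none":
        sigma = np.zeros_like(uf)
    elif model.kind == "standard":
        return model.c_std * u
    elif model.kind == "extended":
        sigma = (model.c_iso * np.abs(uf - ue) ** model.p_iso
                 + model.c_co * np.minimum(uf, ue) ** model.p_co)
    else:  # pragma: no cover - validated at config time
        raise ValueError(f"unknown noise kind {model.kind!r}")
    return np.stack([sigma, sigma], axis=-1)


def external_force_torque(q, fx: float, params: ArmParameters):
    """Joint torque of a constant horizontal endpoint force.

    The endpoint sits at p = L (sin q, cos q); the transposed-Jacobian torque
    of a force fx along x is fx * L * cos(q).
    """
    return fx * params.forearm_length * np.cos(np.asarray(q, dtype=float))


def forward_dynamics(x, u, params: ArmParameters, external_fx: float = 0.0):
    """Deterministic joint acceleration (mean dynamics).

    ``x`` has trailing axis (q, qdot); ``u`` trailing axis (u_f, u_e).
    """
    x = np.asarray(x, dtype=float)
    q, qdot = x[..., 0], x[..., 1]
    lengths, velocities = muscle_geometry(q, qdot, params)
    tau = joint_torque(muscle_tension(u, lengths, velocities, params), params)
    if external_fx != 0.0:
        tau = tau + external_force_torque(q, external_fx, params)
    return tau / params.inertia


def acceleration_noise_std(u, params: ArmParameters, model: NoiseModel):
    """Std of the realized acceleration at one Euler-Maruyama step.

    Tension perturbations eps_i ~ N(0, sigma_i^2) propagate through the
    moment arms and inertia with a 1/sqrt(dt) diffusion scaling, so
    Var(qddot) = (a_f^2 s_f^2 + a_e^2 s_e^2) / (M^2 dt).
    """
    sigma = tension_noise_std(u, model)
    a_f, a_e = params.moment_arms
    var = (a_f ** 2 * sigma[..., 0] ** 2 + a_e ** 2 * sigma[..., 1] ** 2)
    return np.sqrt(var / params.dt) / params.inertia


def _advance(x: np.ndarray, qddot: float, params: ArmParameters) -> Tuple[np.ndarray, bool]:
    """Explicit Euler step with joint-limit clipping (velocity zeroed)."""
    q, qdot = x
    q_next = q + params.dt * qdot
    qdot_next = qdot + params.dt * qddot
    lo, hi = params.q_limits
    hit = False
    if q_next < lo or q_next > hi:
        q_next = np.clip(q_next, lo, hi)
        qdot_next = 0.0
        hit = True
    return np.array([q_next, qdot_next]), hit


def step_stochastic(
    x,
    u,
    params: ArmParameters,
    model: NoiseModel,
    rng: Optional[np.random.Generator],
    external_fx: float = 0.0,
):
    """One Euler-Maruyama step of the stochastic plant.

    Returns ``(x_next, qddot_realized, limit_hit)``.  With ``kind='none'``
    this is bit-for-bit the deterministic Euler step (no RNG draw is made).
    """
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    qddot = float(forward_dynamics(x, u, params, external_fx))
    if model.kind != "none":
        sigma = tension_noise_std(u, model)
        eps = rng.normal(0.0, 1.0, size=2) * sigma
        a_f, a_e = params.moment_arms
        qddot += (a_f * eps[0] - a_e * eps[1]) / (params.inertia * np.sqrt(params.dt))
    x_next, hit = _advance(x, qddot, params)
    return x_next, qddot, hit


def simulate_trial(
    policy: Callable[[int, np.ndarray], np.ndarray],
    x0,
    K: int,
    params: ArmParameters,
    model: NoiseModel,
    rng: Optional[np.random.Generator] = None,
    external_fx: float = 0.0,
) -> Trajectory:
    """Closed-loop rollout of ``policy`` for K steps on the stochastic plant.

    Commands are clipped to [0, 1]; realized accelerations are recorded for
    learner updates.  Raises :class:`SimulationDiverged` on non-finite state.
    """
    x = np.asarray(x0, dtype=float).copy()
    states = np.empty((K + 1, 2))
    controls = np.empty((K, 2))
    accels = np.empty(K)
    hits = 0
    states[0] = x
    for k in range(K):
        u = np.clip(np.asarray(policy(k, x), dtype=float), 0.0, 1.0)
        x, qddot, hit = step_stochastic(x, u, params, model, rng, external_fx)
        if not np.all(np.isfinite(x)):
            raise SimulationDiverged(f"non-finite state at step {k}")
        states[k + 1] = x
        controls[k] = u
        accels[k] = qddot
        hits += hit
    return Trajectory(states, controls, accels, params.dt, limit_hits=hits)


def rollout_controls(
    u_seq,
    x0,
    params: ArmParameters,
    external_fx: float = 0.0,
) -> Trajectory:
    """Deterministic rollout of a stored control sequence (noise off)."""
    quiet = NoiseModel(kind="none")
    u_seq = np.asarray(u_seq, dtype=float)
    policy = lambda k, x: u_seq[k]
    return simulate_trial(policy, x0, u_seq.shape[0], params, quiet, None, external_fx)


def joint_stiffness(u, params: ArmParameters):
    """Magnitude of the restoring-torque gradient |d tau / d q| at a posture.

    For the affine muscle geometry this is a_f^2 k(u_f) + a_e^2 k(u_e):
    symmetric co-contraction stiffens the joint linearly in the commands.
    """
    u = np.asarray(u, dtype=float)
    a_f, a_e = params.moment_arms
    return (a_f ** 2 * (params.k0 + params.k1 * u[..., 0])
            + a_e ** 2 * (params.k0 + params.k1 * u[..., 1]))
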