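"""Parameter schemas, defaults and reproducible random streams.

Every tunable quantity of the arm plant, the noise model, the dynamics
learner, the trajectory optimizer and the experiment protocols lives in a
dataclass here.  The defaults are the versioned reference configuration used
throughout the test-suite and the experiment presets; everything is
overridable from YAML (see :func:`load_config`).

Randomness policy: a single integer seed fans out into named, independent
child streams (:func:`seed_stream`).  No code in this package touches numpy's
global RNG.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, fields
from typing import Any, Tuple

import numpy as np
import yaml

__all__ = [
    "ArmParameters",
    "NoiseModel",
    "BabbleConfig",
    "LearnerConfig",
    "CostSpec",
    "SolverOptions",
    "AdaptationSchedule",
    "ExperimentConfig",
    "ConfigError",
    "seed_stream",
    "load_config",
    "dump_config",
    "config_to_dict",
]


class ConfigError(ValueError):
    """A configuration value failed schema validation."""


def seed_stream(seed: int, *names: str) -> np.random.Generator:
    """Derive a named, independent random generator from a single seed.

    The child entropy is ``[seed, sha256(name)…]`` so that streams with
    different names are statistically independent and a given
    ``(seed, names)`` pair is reproducible across platforms and sessions.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for name in names:
        digest = hashlib.sha256(name.encode("utf-8")).digest()
        entropy.append(int.from_bytes(digest[:8], "little") & 0x7FFFFFFFFFFFFFFF)
    return np.random.default_rng(entropy)


# ---------------------------------------------------------------------------
# Plant
# ---------------------------------------------------------------------------

@dataclass
class ArmParameters:
    """Biomechanical constants of the single-joint antagonistic elbow.

    The two muscles (index 0 = flexor, 1 = extensor) are linear spring-dampers
    whose stiffness ``k(u) = k0 + k1 u``, viscosity ``b(u) = b0 + b1 u`` and
    rest-length shortening ``r u`` all scale linearly with the neural command.
    Moment arms are constant; flexion is the positive joint direction and the
    reference posture q = 0 sits mid-range.
    """

    inertia: float = 0.065            # kg m^2
    moment_arms: Tuple[float, float] = (0.025, 0.025)  # m (flexor, extensor)
    k0: float = 1000.0                # N/m  elasticity intercept
    k1: float = 3000.0                # N/m  elasticity activation gain
    b0: float = 50.0                  # N s/m viscosity intercept
    b1: float = 100.0                 # N s/m viscosity activation gain
    r: float = 0.05                   # m    rest-length shortening per unit u
    ref_lengths: Tuple[float, float] = (0.30, 0.30)    # m at q = 0
    forearm_length: float = 0.35      # m, endpoint lever for external forces
    q_limits: Tuple[float, float] = (-1.9, 1.9)        # rad
    dt: float = 0.01                  # s, integration step

    def validate(self) -> "ArmParameters":
        if self.inertia <= 0:
            raise ConfigError("inertia must be > 0")
        for name in ("k0", "k1", "b0", "b1", "r", "forearm_length", "dt"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if any(a <= 0 for a in self.moment_arms):
            raise ConfigError("moment_arms must be > 0")
        lo, hi = self.q_limits
        if not (lo < 0.0 < hi):
            raise ConfigError("q_limits must be a non-empty interval containing 0")
        return self


@dataclass
class NoiseModel:
    """Signal-dependent noise at the muscle-tension level.

    ``standard``: sigma_i = c_std * u_i  (each muscle scales with its own
    command — co-contraction buys nothing).

    ``extended``: sigma = c_iso * |u_f - u_e|**p_iso + c_co * min(u)**p_co,
    identical for both muscles with independent draws.  The reciprocal
    (isotonic) term dominates the co-contraction (isometric) term, producing
    the valley of reduced noise along the co-contraction diagonal: for a fixed
    net torque, co-activating both muscles stiffens the joint and shrinks the
    reciprocal command needed, hence the tension noise.
    """

    kind: str = "extended"            # none | standard | extended
    c_std: float = 9.0                # N
    c_iso: float = 9.0                # N
    c_co: float = 0.9                 # N
    p_iso: float = 1.5
    p_co: float = 1.0

    def validate(self) -> "NoiseModel":
        if self.kind not in ("none", "standard", "extended"):
            raise ConfigError(f"unknown noise kind {self.kind!r}")
        for name in ("c_std", "c_iso", "c_co"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.p_iso <= 0 or self.p_co <= 0:
            raise ConfigError("SDN exponents must be > 0")
        if self.kind == "extended" and not self.c_iso > self.c_co:
            raise ConfigError("extended SDN requires c_iso > c_co")
        return self


# ---------------------------------------------------------------------------
# Learner
# ---------------------------------------------------------------------------

@dataclass
class BabbleConfig:
    """Motor-babbling protocol used to pre-train the forward model.

    Episodes restart from uniformly drawn states with uniformly drawn
    activations; within an episode the activations follow a clipped Gaussian
    random walk while the stochastic plant is stepped forward, so the samples
    cover the (q, qdot, u) box along dynamically feasible paths.
    """

    n_samples: int = 50_000
    q_range: Tuple[float, float] = (-1.5, 1.5)      # rad
    qdot_range: Tuple[float, float] = (-6.0, 6.0)   # rad/s
    walk_sigma: float = 0.08          # per-step std of the activation walk
    episode_length: int = 25          # steps between state/activation resets

    def validate(self) -> "BabbleConfig":
        if self.n_samples <= 0:
            raise ConfigError("n_samples must be > 0")
        if self.episode_length <= 0:
            raise ConfigError("episode_length must be > 0")
        if self.walk_sigma <= 0:
            raise ConfigError("walk_sigma must be > 0")
        for name in ("q_range", "qdot_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigError(f"{name} must be an increasing interval")
        return self


@dataclass
class LearnerConfig:
    """Hyperparameters of the receptive-field regression forward model.

    Inputs (q, qdot, u_f, u_e) are rescaled by ``norm_scales`` before any
    locality computation; receptive fields are isotropic Gaussians of width
    ``kernel_width`` in that normalized space.  A new field is allocated
    whenever no existing field is activated above ``w_gen``.  Each field runs
    a weighted recursive-least-squares local linear fit with a forgetting
    factor annealed from 1 (young field: accumulate) down to ``forget_min``
    (mature field: track changes, e.g. a novel force field).  The predictive
    variance is the activation-weighted local residual variance plus a
    data-sparsity term that decays with local support.
    """

    norm_scales: Tuple[float, float, float, float] = (1.0, 4.0, 0.5, 0.5)
    kernel_width: float = 0.50        # normalized units
    w_gen: float = 0.50               # allocation threshold
    w_update: float = 0.01            # fields below this skip the update
    init_P: float = 100.0             # RLS prior covariance scale
    forget_min: float = 0.985         # forgetting floor per unit weight
    anneal_weight: float = 120.0      # support at which forgetting kicks in
    prior_noise: float = 100.0        # (rad/s^2)^2 residual-variance prior
    prior_count: float = 1.0          # pseudo-count behind prior_noise
    sparsity_variance: float = 2000.0  # (rad/s^2)^2 ceiling of sparsity term
    sparsity_support: float = 0.25    # support scale of the sparsity decay
    support_min: float = 0.05         # below this a query is "no support"

    def validate(self) -> "LearnerConfig":
        if any(s <= 0 for s in self.norm_scales):
            raise ConfigError("norm_scales must be > 0")
        if not 0 < self.kernel_width:
            raise ConfigError("kernel_width must be > 0")
        if not 0 < self.w_update < self.w_gen < 1:
            raise ConfigError("need 0 < w_update < w_gen < 1")
        if not 0 < self.forget_min <= 1:
            raise ConfigError("forget_min must be in (0, 1]")
        for name in ("init_P", "anneal_weight", "prior_noise", "prior_count",
                     "sparsity_variance", "sparsity_support", "support_min"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        return self


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

@dataclass
class CostSpec:
    """Reaching-task cost: final accuracy, final stability, energy.

    total = w_p (q_K - q_target)^2 + w_v qdot_K^2 + w_e sum_k ||u_k||^2 dt
    """

    w_p: float = 1.0e5                # rad^-2
    w_v: float = 1.0e3                # (rad/s)^-2
    w_e: float = 1.0
    q_target: float = 0.5             # rad
    K: int = 50
    dt: float = 0.01                  # s

    def validate(self) -> "CostSpec":
        if min(self.w_p, self.w_v, self.w_e) < 0:
            raise ConfigError("cost weights must be >= 0")
        if self.K < 1:
            raise ConfigError("K must be >= 1")
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")
        return self


@dataclass
class SolverOptions:
    """iLQG iteration controls (regularization, line search, tolerances)."""

    max_iter: int = 50            # per continuation stage
    tol: float = 1.0e-6               # relative expected-cost change
    reg_init: float = 0.0             # Levenberg-Marquardt lambda
    reg_grow: float = 10.0
    reg_shrink: float = 0.5
    reg_floor: float = 1.0e-9
    reg_max: float = 1.0e8
    fd_step: float = 1.0e-4           # central-difference step
    line_search_decay: float = 0.5
    line_search_steps: int = 10
    noise_stages: int = 4             # continuation stages on the noise scale

    def validate(self) -> "SolverOptions":
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if self.tol <= 0 or self.fd_step <= 0:
            raise ConfigError("tol and fd_step must be > 0")
        if self.reg_grow <= 1 or not 0 < self.line_search_decay < 1:
            raise ConfigError("bad regularization/line-search schedule")
        return self


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

@dataclass
class AdaptationSchedule:
    """Null-field / force-field reaching protocol.

    The force field is a constant endpoint force applied along the reach
    (here an extension movement, target -0.5 rad), so the adapted controller
    can exploit it: the reach's agonist relaxes and the brake/hold muscle
    works against the field.
    """

    n_nullfield_trials: int = 5
    n_forcefield_trials: int = 20
    ff_force: float = -4.0            # N endpoint force (sign: along the reach)
    replications: int = 20
    q_target: float = -0.5            # rad
    replay_passes: int = 10           # per-trial learner replay passes
    # reaching weights for this protocol: compliant enough that the first
    # force-field exposure visibly deflects the arm
    w_p: float = 1.0e4
    w_v: float = 1.0e2

    def validate(self) -> "AdaptationSchedule":
        for name in ("n_nullfield_trials", "n_forcefield_trials",
                     "replications", "replay_passes"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        return self


@dataclass
class ExperimentConfig:
    """Top-level bundle consumed by the experiment drivers and the CLI."""

    arm: ArmParameters = field(default_factory=ArmParameters)
    noise: NoiseModel = field(default_factory=NoiseModel)
    babble: BabbleConfig = field(default_factory=BabbleConfig)
    learner: LearnerConfig = field(default_factory=LearnerConfig)
    cost: CostSpec = field(default_factory=CostSpec)
    solver: SolverOptions = field(default_factory=SolverOptions)
    adaptation: AdaptationSchedule = field(default_factory=AdaptationSchedule)
    # per-experiment protocol knobs
    n_trials_sdn: int = 50            # noise-model comparison
    n_trials_condition: int = 20      # accuracy/velocity sweeps
    accuracy_scales: Tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    velocity_targets: Tuple[float, ...] = (0.2, 0.5, 0.8)   # rad

    def validate(self) -> "ExperimentConfig":
        for f in fields(self):
            value = getattr(self, f.name)
            if hasattr(value, "validate"):
                value.validate()
        if self.n_trials_sdn < 1 or self.n_trials_condition < 1:
            raise ConfigError("trial counts must be >= 1")
        if len(self.accuracy_scales) < 2 or len(self.velocity_targets) < 2:
            raise ConfigError("sweeps need at least two conditions")
        return self


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

def _from_dict(cls: type, data: dict, path: str) -> Any:
    if not isinstance(data, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"{path or 'config'}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        sub = f.default_factory() if f.default_factory is not dataclasses.MISSING else None  # type: ignore[misc]
        if dataclasses.is_dataclass(sub):
            kwargs[name] = _from_dict(type(sub), value, f"{path}.{name}".lstrip("."))
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def config_to_dict(config: Any) -> dict:
    """Dataclass tree -> plain dict (tuples as lists) for YAML/JSON."""
    out: dict = {}
    for f in fields(config):
        value = getattr(config, f.name)
        if dataclasses.is_dataclass(value):
            out[f.name] = config_to_dict(value)
        elif isinstance(value, tuple):
            out[f.name] = list(value)
        else:
            out[f.name] = value
    return out


def load_config(path: str | None = None, text: str | None = None) -> ExperimentConfig:
    """Load and validate an :class:`ExperimentConfig` from YAML.

    Missing keys fall back to the documented defaults; unknown keys are
    rejected with the offending field path.  An empty file yields the full
    default configuration.
    """
    if text is None:
        if path is None:
            raise ConfigError("either path or text must be given")
        with open(path, "r", encoding="utf-8") as handle:
            text = handle.read()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    config = _from_dict(ExperimentConfig, data, "")
    return config.validate()


def dump_config(config: ExperimentConfig) -> str:
    """Serialize a configuration to YAML (inverse of :func:`load_config`)."""
    return yaml.safe_dump(config_to_dict(config), sort_keys=False)
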