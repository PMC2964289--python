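"""Incremental learned forward model with heteroscedastic uncertainty.

The plant's stochastic forward dynamics (q, qdot, u_f, u_e) -> qddot is
approximated by an ensemble of Gaussian receptive fields, each holding a
local linear model fitted by weighted recursive least squares.  The design
follows the receptive-field weighted regression family (LWPR without the
input-projection machinery, which a 4-D problem does not need):

* fields are allocated online wherever no existing field is activated above a
  generation threshold, so the model grows with the explored region;
* every update is constant-cost (only activated fields touch their 5x5 RLS
  state), satisfying the streaming contract;
* each field tracks a forgetting-weighted residual variance, and prediction
  variance = activation-weighted residual variance + a sparsity term that
  decays with local support.  Variance therefore grows both where the output
  noise is large (signal-dependent motor noise) and where training data is
  thin or the dynamics have drifted (novel force field) — the quantity the
  stochastic optimal controller consumes as model uncertainty.

The forgetting factor is annealed per field from 1 (young field: accumulate)
to a floor (mature field: track change), reconciling pre-training accuracy
with adaptation speed.
"""

from __future__ import annotations

from typing import Optional, Tuple

import h5py
import numpy as np

from .config import ArmParameters, BabbleConfig, LearnerConfig, NoiseModel
from . import plant

__all__ = [
    "LearnedDynamics",
    "create_learner",
    "generate_babble_data",
    "model_nmse",
    "save_learner",
    "load_learner",
]

_DIM = 4          # (q, qdot, u_flexor, u_extensor)
_NPAR = _DIM + 1  # local model: intercept + linear terms


class LearnedDynamics:
    """Receptive-field regression model of the stochastic forward dynamics."""

    def __init__(self, config: LearnerConfig):
        self.config = config.validate()
        self.n_updates = 0
        self._n = 0
        cap = 64
        self._centers = np.empty((cap, _DIM))        # normalized input space
        self._beta = np.empty((cap, _NPAR))          # [intercept, slopes]
        self._P = np.empty((cap, _NPAR, _NPAR))      # RLS covariance
        self._W = np.empty(cap)                      # forgetting-weighted support
        self._sres = np.empty(cap)                   # weighted residual SS
        self._wres = np.empty(cap)                   # weight behind _sres
        self._scales = np.asarray(config.norm_scales, dtype=float)

    # -- bookkeeping --------------------------------------------------------

    @property
    def n_fields(self) -> int:
        return self._n

    def copy(self) -> "LearnedDynamics":
        other = LearnedDynamics(self.config)
        other.n_updates = self.n_updates
        other._n = self._n
        for name in ("_centers", "_beta", "_P", "_W", "_sres", "_wres"):
            setattr(other, name, getattr(self, name).copy())
        return other

    def _grow(self) -> None:
        for name in ("_centers", "_beta", "_P", "_W", "_sres", "_wres"):
            arr = getattr(self, name)
            setattr(self, name, np.concatenate([arr, np.empty_like(arr)], axis=0))

    def _normalize(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) / self._scales

    def _add_field(self, zn: np.ndarray, y: float) -> None:
        if self._n == self._centers.shape[0]:
            self._grow()
        i = self._n
        self._centers[i] = zn
        self._beta[i] = 0.0
        self._beta[i, 0] = y
        self._P[i] = np.eye(_NPAR) * self.config.init_P
        self._W[i] = 1e-3
        self._sres[i] = 0.0
        self._wres[i] = 1e-3
        self._n += 1

    def _activations(self, zn: np.ndarray) -> np.ndarray:
        """Gaussian kernel weights of all fields at one normalized input."""
        diff = self._centers[: self._n] - zn
        d2 = np.einsum("kj,kj->k", diff, diff)
        return np.exp(-0.5 * d2 / self.config.kernel_width ** 2)

    # -- learning -----------------------------------------------------------

    def update(self, z, y: float, learn_variance: bool = True) -> None:
        """Incrementally absorb one sample (state-action z, acceleration y).

        Constant-bounded cost: only fields activated above ``w_update`` are
        touched; a new field is allocated if none reaches ``w_gen``.  With
        ``learn_variance=False`` only the local means are refined and the
        residual-variance statistics are left untouched — used when replaying
        on-policy movement data whose narrow command distribution would
        otherwise wash out the exploration-calibrated noise landscape.
        """
        z = np.asarray(z, dtype=float).ravel()
        y = float(y)
        if z.shape != (_DIM,) or not (np.all(np.isfinite(z)) and np.isfinite(y)):
            raise ValueError(f"invalid training sample: z={z!r}, y={y!r}")
        zn = self._normalize(z)
        cfg = self.config
        w = self._activations(zn) if self._n else np.empty(0)
        if self._n == 0 or w.max() < cfg.w_gen:
            self._add_field(zn, y)
            w = self._activations(zn)
        idx = np.nonzero(w > cfg.w_update)[0]
        wa = w[idx]

        # annealed per-field forgetting, applied in proportion to the weight
        lam_field = cfg.forget_min + (1.0 - cfg.forget_min) * np.exp(
            -self._W[idx] / cfg.anneal_weight)
        lam = np.exp(wa * np.log(lam_field))

        diff = zn - self._centers[idx]                       # (k, 4)
        phi = np.concatenate([np.ones((idx.size, 1)), diff], axis=1)  # (k, 5)
        P = self._P[idx]
        Pphi = np.einsum("kij,kj->ki", P, phi)
        denom = lam + wa * np.einsum("ki,ki->k", phi, Pphi)
        e_pre = y - np.einsum("ki,ki->k", phi, self._beta[idx])
        gain = (wa / denom)[:, None] * Pphi
        self._beta[idx] += gain * e_pre[:, None]
        P_new = (P - np.einsum("ki,kj->kij", gain, Pphi)) / lam[:, None, None]
        # keep P symmetric and bounded (rarely excited fields would drift up)
        P_new = 0.5 * (P_new + np.swapaxes(P_new, 1, 2))
        tr = np.einsum("kii->k", P_new)
        cap = _NPAR * cfg.init_P * 10.0
        scale = np.minimum(1.0, cap / np.maximum(tr, 1e-12))
        self._P[idx] = P_new * scale[:, None, None]

        self._W[idx] = lam * self._W[idx] + wa
        if learn_variance:
            self._sres[idx] = lam * self._sres[idx] + wa * e_pre ** 2
            self._wres[idx] = lam * self._wres[idx] + wa
        self.n_updates += 1

    def update_batch(self, Z: np.ndarray, Y: np.ndarray, passes: int = 1,
                     learn_variance: bool = True) -> None:
        for _ in range(passes):
            for z, y in zip(np.asarray(Z, dtype=float), np.asarray(Y, dtype=float)):
                self.update(z, y, learn_variance=learn_variance)

    # -- prediction ---------------------------------------------------------

    def predict(self, Z) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Localized mean, predictive variance and support at query points.

        ``Z`` is (..., 4).  Returns arrays of shape (...,).  Queries without
        local support yield mean 0, the maximal (sparsity-ceiling) variance
        and support below ``support_min`` — callers treat that as a flagged
        no-support result.
        """
        Z = np.asarray(Z, dtype=float)
        scalar = Z.ndim == 1
        Zn = np.atleast_2d(self._normalize(Z))
        flat = Zn.reshape(-1, _DIM)
        mean = np.zeros(flat.shape[0])
        var = np.full(flat.shape[0], self.config.sparsity_variance)
        support = np.zeros(flat.shape[0])
        if self._n:
            for start in range(0, flat.shape[0], 1024):
                sl = slice(start, start + 1024)
                m, v, s = self._predict_chunk(flat[sl])
                mean[sl], var[sl], support[sl] = m, v, s
        shape = Z.shape[:-1]
        mean, var, support = (a.reshape(shape) for a in (mean, var, support))
        if scalar:
            return float(mean), float(var), float(support)
        return mean, var, support

    def _predict_chunk(self, Zn: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        cfg = self.config
        n = self._n
        diff = Zn[:, None, :] - self._centers[None, :n, :]     # (m, n, 4)
        d2 = np.einsum("mkj,mkj->mk", diff, diff)
        w = np.exp(-0.5 * d2 / cfg.kernel_width ** 2)          # (m, n)
        yk = self._beta[:n, 0] + np.einsum("mkj,kj->mk", diff, self._beta[:n, 1:])
        wsum = w.sum(axis=1)
        safe = np.maximum(wsum, 1e-12)
        mean = np.where(wsum > 1e-12, (w * yk).sum(axis=1) / safe, 0.0)
        sigma2 = (self._sres[:n] + cfg.prior_noise * cfg.prior_count) / (
            self._wres[:n] + cfg.prior_count)
        noise_var = np.where(wsum > 1e-12, (w * sigma2).sum(axis=1) / safe, 0.0)
        # support: kernel mass, discounted for fields that hold little data

        maturity = self._W[:n] / (self._W[:n] + 2.0)
        support = (w * maturity).sum(axis=1)
        sparsity = cfg.sparsity_variance * np.exp(-support / cfg.sparsity_support)
        return mean, noise_var + sparsity, support

    def predict_one(self, z: np.ndarray) -> Tuple[float, float, float]:
        """Low-overhead scalar prediction (hot path of closed-loop rollouts)."""
        cfg = self.config
        if self._n == 0:
            return 0.0, cfg.sparsity_variance, 0.0
        zn = np.asarray(z, dtype=float) / self._scales
        n = self._n
        diff = zn - self._centers[:n]
        w = np.exp(-0.5 * np.einsum("kj,kj->k", diff, diff) / cfg.kernel_width ** 2)
        wsum = w.sum()
        yk = self._beta[:n, 0] + np.einsum("kj,kj->k", diff, self._beta[:n, 1:])
        mean = float(w @ yk / wsum) if wsum > 1e-12 else 0.0
        sigma2 = (self._sres[:n] + cfg.prior_noise * cfg.prior_count) / (
            self._wres[:n] + cfg.prior_count)
        noise_var = float(w @ sigma2 / wsum) if wsum > 1e-12 else 0.0
        support = float(w @ (self._W[:n] / (self._W[:n] + 2.0)))
        sparsity = cfg.sparsity_variance * np.exp(-support / cfg.sparsity_support)
        return mean, noise_var + sparsity, support

    def mean_fn(self):
        """Batched (X, U) -> acceleration mean, for the control problem."""
        def fn(X: np.ndarray, U: np.ndarray) -> np.ndarray:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                z = np.empty(_DIM)
                z[:2], z[2:] = X, U
                return self.predict_one(z)[0]
            Z = np.concatenate([X, U], axis=-1)
            return self.predict(Z)[0]
        return fn

    def std_fn(self):
        """Batched (X, U) -> acceleration predictive std."""
        def fn(X: np.ndarray, U: np.ndarray) -> np.ndarray:
            Z = np.concatenate([X, U], axis=-1)
            return np.sqrt(self.predict(Z)[1])
        return fn


def create_learner(config: Optional[LearnerConfig] = None) -> LearnedDynamics:
    """Fresh (empty) forward model; any query is flagged no-support."""
    return LearnedDynamics(config or LearnerConfig())


# ---------------------------------------------------------------------------
# Motor babbling
# ---------------------------------------------------------------------------

def generate_babble_data(
    params: ArmParameters,
    noise: NoiseModel,
    config: BabbleConfig,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Exploratory dataset covering the (q, qdot, u) box.

    Episodes restart from uniform states/activations; within an episode the
    activations follow a clipped Gaussian random walk and the stochastic
    plant supplies realized accelerations as regression targets.  Returns
    ``(Z, Y)`` with Z of shape (n, 4) and Y of shape (n,).
    """
    config.validate()
    n = config.n_samples
    Z = np.empty((n, _DIM))
    Y = np.empty(n)
    q_lo, q_hi = config.q_range
    v_lo, v_hi = config.qdot_range
    x = np.zeros(2)
    u = np.zeros(2)
    episode = -1
    for i in range(n):
        if i % config.episode_length == 0:
            episode += 1
            # alternate fast and near-stationary starts: quasi-static
            # movements ride the muscle slack/taut boundary, and the forward
            # model needs dense data on that manifold
            if episode % 2 == 0:
                qd0 = rng.uniform(v_lo, v_hi)
            else:
                qd0 = rng.uniform(max(v_lo, -1.0), min(v_hi, 1.0))
            x = np.array([rng.uniform(q_lo, q_hi), qd0])
            u = rng.uniform(0.0, 1.0, size=2)
        else:
            u = np.clip(u + rng.normal(0.0, config.walk_sigma, size=2), 0.0, 1.0)
        Z[i, :2] = x
        Z[i, 2:] = u
        x, qddot, _ = plant.step_stochastic(x, u, params, noise, rng)
        Y[i] = qddot
        # keep the walk inside the configured state box
        if not (q_lo <= x[0] <= q_hi and v_lo <= x[1] <= v_hi):
            x = np.array([np.clip(x[0], q_lo, q_hi), np.clip(x[1], v_lo, v_hi)])
    return Z, Y


def model_nmse(model: LearnedDynamics, Z: np.ndarray, Y: np.ndarray) -> float:
    """Mean squared prediction error normalized by the target variance."""
    Y = np.asarray(Y, dtype=float)
    if Y.size == 0:
        raise ValueError("empty evaluation dataset")
    var = float(np.var(Y))
    if var <= 0.0:
        raise ValueError("zero-variance evaluation dataset")
    mean, _, _ = model.predict(np.asarray(Z, dtype=float))
    return float(np.mean((mean - Y) ** 2) / var)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_learner(model: LearnedDynamics, path: str) -> None:
    """Serialize model state + hyperparameters to an HDF5 container."""
    from dataclasses import asdict

    with h5py.File(path, "w") as f:
        f.attrs["n_updates"] = model.n_updates
        f.attrs["n_fields"] = model._n
        for key, value in asdict(model.config).items():
            f.attrs[f"config:{key}"] = value
        n = model._n
        f.create_dataset("centers", data=model._centers[:n])
        f.create_dataset("beta", data=model._beta[:n])
        f.create_dataset("P", data=model._P[:n])
        f.create_dataset("W", data=model._W[:n])
        f.create_dataset("sres", data=model._sres[:n])
        f.create_dataset("wres", data=model._wres[:n])


def load_learner(path: str) -> LearnedDynamics:
    """Inverse of :func:`save_learner`."""
    from dataclasses import fields as dc_fields

    with h5py.File(path, "r") as f:
        kwargs = {}
        for fld in dc_fields(LearnerConfig):
            raw = f.attrs[f"config:{fld.name}"]
            kwargs[fld.name] = tuple(raw) if isinstance(raw, np.ndarray) else raw.item() if hasattr(raw, "item") else raw
        model = LearnedDynamics(LearnerConfig(**kwargs))
        n = int(f.attrs["n_fields"])
        model.n_updates = int(f.attrs["n_updates"])
        cap = max(64, n)
        model._centers = np.empty((cap, _DIM)); model._centers[:n] = f["centers"][...]
        model._beta = np.empty((cap, _NPAR)); model._beta[:n] = f["beta"][...]
        model._P = np.empty((cap, _NPAR, _NPAR)); model._P[:n] = f["P"][...]
        model._W = np.empty(cap); model._W[:n] = f["W"][...]
        model._sres = np.empty(cap); model._sres[:n] = f["sres"][...]
        model._wres = np.empty(cap); model._wres[:n] = f["wres"][...]
        model._n = n
    return model
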