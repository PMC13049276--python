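"""Discrete diffusion machinery.

A variance-preserving diffusion process on latents, discretized into ``T``
steps with per-step noise increments ``beta[t]`` and cumulative noise factor
``alpha_bar[t]`` (the fraction of signal variance surviving at step ``t``):

    z_t = sqrt(alpha_bar[t]) * z_0 + sqrt(1 - alpha_bar[t]) * eps,   eps ~ N(0, I)

Models follow the eps-prediction convention: a :class:`ScoreModel` maps
``(z_t, t)`` to an estimate of the noise field ``eps``, from which the
posterior-mean denoised latent follows by Tweedie's formula.  Sampling is
done with DDIM steps on a sub-grid of timesteps (deterministic at
``eta=0``), with ancestral DDPM stepping available for cross-checks.

Besides trained networks, analytic score oracles for Gaussian latent priors
are provided; these make every sampler property testable against closed
forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from ._nn import Adam, ConvNet, MLPNet

__all__ = [
    "NoiseSchedule",
    "ScoreModel",
    "GaussianPriorSpec",
    "make_schedule",
    "forward_noise",
    "tweedie_denoise",
    "ddim_step",
    "ancestral_step",
    "ddim_grid",
    "ddim_sample",
    "ancestral_sample",
    "gaussian_oracle",
    "train_score_model",
]


@dataclass
class NoiseSchedule:
    """Discrete diffusion parameters.

    ``alpha_bar`` has length T+1 with index 0 meaning "clean"; ``gamma`` is
    the per-dimension log-normalizer of the hot-start objective,
    ``gamma[t] = -0.5 * log(1 - alpha_bar[t]**2)`` (infinite at t=0).
    """

    T: int
    beta: np.ndarray
    alpha_bar: np.ndarray
    gamma: np.ndarray

    def __post_init__(self):
        if len(self.beta) != self.T or len(self.alpha_bar) != self.T + 1:
            raise ValueError("schedule arrays inconsistent with T")


def make_schedule(T: int, beta_min: float = 1e-4, beta_max: float = 0.02) -> NoiseSchedule:
    """Linear-beta schedule; the default endpoints are the common DDPM choice."""
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if not (0 < beta_min <= beta_max < 1):
        raise ValueError(f"require 0 < beta_min <= beta_max < 1, got ({beta_min}, {beta_max})")
    beta = np.linspace(beta_min, beta_max, T)
    alpha_bar = np.concatenate([[1.0], np.cumprod(1.0 - beta)])
    with np.errstate(divide="ignore"):
        gamma = -0.5 * np.log(1.0 - alpha_bar ** 2)
    return NoiseSchedule(T=T, beta=beta, alpha_bar=alpha_bar, gamma=gamma)


@dataclass
class GaussianPriorSpec:
    """Diagonal Gaussian latent prior N(mean, diag(var)); used by test oracles."""

    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.var = np.asarray(self.var, dtype=np.float64)
        if np.any(self.var <= 0):
            raise ValueError("variances must be strictly positive")

    @property
    def d(self) -> int:
        return self.mean.size


@dataclass
class ScoreModel:
    """eps-prediction model: callable (z_t, t) -> predicted noise of same shape.

    ``vjp(z, t, u)`` returns J_eps(z,t)^T u, the input-side vector-Jacobian
    product needed by the latent data-consistency gradient.
    """

    eps_fn: Callable[[np.ndarray, int], np.ndarray]
    vjp_fn: Optional[Callable[[np.ndarray, int, np.ndarray], np.ndarray]] = None
    analytic: bool = False
    meta: dict = field(default_factory=dict)
    net: object = None

    def eps(self, z: np.ndarray, t: int) -> np.ndarray:
        out = self.eps_fn(z, t)
        if out.shape != z.shape:
            raise RuntimeError("score model changed latent shape")
        return out

    def vjp(self, z: np.ndarray, t: int, u: np.ndarray) -> np.ndarray:
        if self.vjp_fn is None:
            raise NotImplementedError("model has no input-gradient path")
        return self.vjp_fn(z, t, u)

    def __call__(self, z, t):
        return self.eps(z, t)


def gaussian_oracle(schedule: NoiseSchedule, prior: Optional[GaussianPriorSpec] = None) -> ScoreModel:
    """Analytic eps-predictor for a diagonal Gaussian latent prior.

    For z0 ~ N(mu, diag(v)) the marginal at t is
    N(sqrt(ab)*mu, ab*v + (1-ab)), so the exact noise prediction is

        eps_hat = sqrt(1-ab) * (z - sqrt(ab)*mu) / (ab*v + (1-ab))

    which reduces to ``sqrt(1-ab) * z`` for the standard normal prior.
    """
    ab = schedule.alpha_bar

    if prior is None:
        def eps_fn(z, t):
            return np.sqrt(1.0 - ab[t]) * z

        def vjp_fn(z, t, u):
            return np.sqrt(1.0 - ab[t]) * u

        return ScoreModel(eps_fn, vjp_fn, analytic=True, meta={"prior": "N(0,I)"})

    mu, v = prior.mean, prior.var

    def eps_fn(z, t):
        den = ab[t] * v + (1.0 - ab[t])
        return np.sqrt(1.0 - ab[t]) * (z - np.sqrt(ab[t]) * mu) / den

    def vjp_fn(z, t, u):
        den = ab[t] * v + (1.0 - ab[t])
        return np.sqrt(1.0 - ab[t]) * u / den

    return ScoreModel(eps_fn, vjp_fn, analytic=True, meta={"prior": "diag-gaussian"})


# ---------------------------------------------------------------------------
# forward / reverse steps
# ---------------------------------------------------------------------------

def _check_t(t, T):
    if not (0 <= t <= T):
        raise ValueError(f"timestep {t} outside [0, {T}]")


def forward_noise(z0: np.ndarray, t: int, schedule: NoiseSchedule,
                  seed: Optional[int] = None, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Project a clean latent to timestep t by noising; deterministic per seed."""
    _check_t(t, schedule.T)
    if t == 0:
        return np.array(z0, copy=True)
    if rng is None:
        rng = np.random.default_rng(seed)
    ab = schedule.alpha_bar[t]
    eps = rng.standard_normal(z0.shape)
    return np.sqrt(ab) * z0 + np.sqrt(1.0 - ab) * eps


def tweedie_denoise(zt: np.ndarray, t: int, model: ScoreModel, schedule: NoiseSchedule) -> np.ndarray:
    """Posterior-mean denoised latent E[z0 | z_t] under eps-prediction."""
    if t < 1:
        raise ValueError("tweedie_denoise requires t >= 1")
    _check_t(t, schedule.T)
    ab = schedule.alpha_bar[t]
    return (zt - np.sqrt(1.0 - ab) * model.eps(zt, t)) / np.sqrt(ab)


def ddim_step(zt: np.ndarray, t: int, t_next: int, model: ScoreModel,
              schedule: NoiseSchedule, eta: float = 0.0,
              rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """One DDIM update from t to t_next < t (t_next == t is an allowed no-op)."""
    _check_t(t, schedule.T)
    _check_t(t_next, schedule.T)
    if t_next > t:
        raise ValueError(f"DDIM step must be non-increasing, got {t} -> {t_next}")
    if not (0.0 <= eta <= 1.0):
        raise ValueError("eta must lie in [0, 1]")
    if t_next == t:
        return np.array(zt, copy=True)
    ab_t = schedule.alpha_bar[t]
    ab_n = schedule.alpha_bar[t_next]
    eps_hat = model.eps(zt, t)
    z0_hat = (zt - np.sqrt(1.0 - ab_t) * eps_hat) / np.sqrt(ab_t)
    sigma = eta * np.sqrt((1.0 - ab_n) / (1.0 - ab_t)) * np.sqrt(1.0 - ab_t / ab_n)
    out = np.sqrt(ab_n) * z0_hat + np.sqrt(max(1.0 - ab_n - sigma ** 2, 0.0)) * eps_hat
    if sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        out = out + sigma * rng.standard_normal(zt.shape)
    return out


def ancestral_step(zt: np.ndarray, t: int, model: ScoreModel, schedule: NoiseSchedule,
                   rng: np.random.Generator) -> np.ndarray:
    """One stochastic DDPM reverse step from t to t-1."""
    if t < 1:
        raise ValueError("ancestral step requires t >= 1")
    beta = schedule.beta[t - 1]
    ab_t = schedule.alpha_bar[t]
    ab_p = schedule.alpha_bar[t - 1]
    eps_hat = model.eps(zt, t)
    mean = (zt - beta / np.sqrt(1.0 - ab_t) * eps_hat) / np.sqrt(1.0 - beta)
    if t > 1:
        var = (1.0 - ab_p) / (1.0 - ab_t) * beta
        return mean + np.sqrt(var) * rng.standard_normal(zt.shape)
    return mean


def ddim_grid(schedule: NoiseSchedule, n_step: int) -> np.ndarray:
    """Uniform timestep grid 0 = t_0 < ... < t_n = T with n_step intervals."""
    grid = np.unique(np.round(np.linspace(0, schedule.T, n_step + 1)).astype(int))
    return grid


def ddim_sample(z_start: np.ndarray, t_start: int, model: ScoreModel, schedule: NoiseSchedule,
                n_step: int = 50, eta: float = 0.0,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Run DDIM from (z_start, t_start) down to t=0 on a uniform grid."""
    grid = ddim_grid(schedule, n_step)
    idx = int(np.argmin(np.abs(grid - t_start)))
    z = z_start
    for k in range(idx, 0, -1):
        z = ddim_step(z, int(grid[k]), int(grid[k - 1]), model, schedule, eta=eta, rng=rng)
    return z


def ancestral_sample(z_start: np.ndarray, t_start: int, model: ScoreModel,
                     schedule: NoiseSchedule, rng: np.random.Generator) -> np.ndarray:
    z = z_start
    for t in range(t_start, 0, -1):
        z = ancestral_step(z, t, model, schedule, rng)
    return z


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_score_model(latents: Sequence[np.ndarray], schedule: NoiseSchedule,
                      epochs: int = 20, seed: int = 0, width: int = 32, depth: int = 2,
                      batch_size: int = 32, lr: float = 2e-3,
                      val_frac: float = 0.1) -> ScoreModel:
    """Train a small eps-prediction network by denoising score matching.

    ``latents`` is a sequence of equally shaped latents, flat (d,) or image
    (H, W, C); an MLP or a small CNN is used accordingly.  Training is fully
    deterministic for a fixed seed.
    """
    data = np.stack([np.asarray(z, dtype=np.float64) for z in latents])
    if data.shape[0] == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    n = data.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_frac * n))) if n > 1 else 0
    val, train = data[perm[:n_val]], data[perm[n_val:]]
    if train.shape[0] == 0:
        train = data[perm]
    if val.shape[0] == 0:
        val = train

    flat = data.ndim == 2
    if flat:
        net = MLPNet(data.shape[1], width=max(width, 2 * data.shape[1]), depth=depth,
                     seed=int(rng.integers(2 ** 31)))
    else:
        net = ConvNet(data.shape[-1], width=width, depth=depth,
                      seed=int(rng.integers(2 ** 31)))

    ab = schedule.alpha_bar

    def batch_loss_and_grads(z0, update=True):
        B = z0.shape[0]
        t = rng.integers(1, schedule.T + 1, size=B)
        eps = rng.standard_normal(z0.shape)
        sq = np.sqrt(ab[t])
        sq1 = np.sqrt(1.0 - ab[t])
        bshape = (B,) + (1,) * (z0.ndim - 1)
        zt = sq.reshape(bshape) * z0 + sq1.reshape(bshape) * eps
        pred, caches = net.forward(zt, t.astype(np.float64))
        diff = pred - eps
        loss = float(np.mean(diff ** 2))
        if not update:
            return loss, None
        grads = net.backward(caches, 2.0 * diff / diff.size)[1]
        return loss, net.grads_flat(grads)

    def eval_loss(z0, rng_eval):
        # fixed-noise validation loss, averaged over a few timestep draws
        saved = rng.bit_generator.state
        total = 0.0
        reps = 4
        for _ in range(reps):
            B = z0.shape[0]
            t = rng_eval.integers(1, schedule.T + 1, size=B)
            eps = rng_eval.standard_normal(z0.shape)
            bshape = (B,) + (1,) * (z0.ndim - 1)
            zt = np.sqrt(ab[t]).reshape(bshape) * z0 + np.sqrt(1 - ab[t]).reshape(bshape) * eps
            pred, _ = net.forward(zt, t.astype(np.float64))
            total += float(np.mean((pred - eps) ** 2))
        rng.bit_generator.state = saved
        return total / reps

    opt = Adam(net.get_flat().size, lr=lr)
    history = {"train": [], "val": []}
    history["val"].append(eval_loss(val, np.random.default_rng(seed + 1)))
    theta = net.get_flat()
    n_train = train.shape[0]
    for ep in range(epochs):
        order = rng.permutation(n_train)
        ep_losses = []
        for s in range(0, n_train, batch_size):
            zb = train[order[s:s + batch_size]]
            loss, g = batch_loss_and_grads(zb)
            theta = opt.step(theta, g)
            net.set_flat(theta)
            ep_losses.append(loss)
        history["train"].append(float(np.mean(ep_losses)))
        history["val"].append(eval_loss(val, np.random.default_rng(seed + 1)))

    def eps_fn(z, t):
        out, _ = net.forward(z[None], np.array([float(t)]))
        return out[0]

    def vjp_fn(z, t, u):
        _, caches = net.forward(z[None], np.array([float(t)]))
        dx, _ = net.backward(caches, u[None])
        return dx[0]

    return ScoreModel(eps_fn, vjp_fn, analytic=False, net=net,
                      meta={"seed": seed, "epochs": epochs, "loss_history": history,
                            "width": width, "depth": depth})
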