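"""Posterior-sampling reconstruction engines.

The core loop is latent diffusion posterior sampling (LDPS): DDIM stepping
of the latent, interleaved with ``n_opt`` adaptive-moment (Adam) descent
updates on the measurement-consistency loss

    || y - A( D( E[z0 | z_t] ) ) ||^2

whose gradient is carried through both Tweedie's formula (including the
score network's input Jacobian) and the decoder.  Two front ends share the
loop:

* ``caps_recon`` — prior-free: initializes from a CG-SENSE reconstruction
  encoded and projected to a fixed timestep (t_p = 200 by default);
* ``laps_recon`` — longitudinal: initializes from the phase-modulated,
  registered prior scan projected to an adaptively selected timestep
  (AutoInit), falling back to pure posterior sampling as t_p -> T.

Because the decoder is lossy, the decoded output is refined by a few
conjugate-gradient data-consistency steps in image space, and the final
image averages ``n_avg`` independently seeded samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from ._nn import Adam
from .codec import Codec, decode, decode_vjp, encode
from .operators import ForwardOperator, MultiCoilKSpace, apply_adjoint, \
    apply_forward, cg_sense
from .schedule import NoiseSchedule, ScoreModel, ddim_grid, ddim_step, \
    forward_noise, tweedie_denoise

__all__ = [
    "ReconConfig",
    "ReconResult",
    "dc_gradient_latent",
    "ldps_sample",
    "hot_started_sample",
    "caps_recon",
    "laps_recon",
    "output_dc",
    "average_samples",
]


@dataclass
class ReconConfig:
    """Hyperparameters of the posterior-sampling reconstructions.

    Defaults follow the reference operating point: n_opt=10 DC steps per
    diffusion step, n_step=100 DDIM steps, n_avg=4 averaged samples, 6 CG
    output-DC iterations; CAPS fixes t_p=200.
    """

    t_p: Union[int, str] = "auto"
    n_step: int = 100
    n_opt: int = 10
    n_avg: int = 4
    n_cg_out: int = 6
    lr: float = 1e-2          # Adam step size on latents (the role of zeta_t)
    lam_dc: float = 1e-2      # output-DC proximity weight
    eta: float = 0.0          # DDIM stochasticity
    seed: int = 0
    t_min: int = 50
    cg_lam: float = 1e-2      # CG-SENSE initializer regularization
    cg_iter: int = 10
    avg_mode: str = "complex"
    register_prior: bool = True

    def __post_init__(self):
        for name in ("n_step", "n_opt", "n_avg", "n_cg_out"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @staticmethod
    def caps(**kw) -> "ReconConfig":
        kw.setdefault("t_p", 200)
        return ReconConfig(**kw)

    @staticmethod
    def fast_init(**kw) -> "ReconConfig":
        """InitReconAlg settings: t_p=200, n_opt=5, n_step=80, n_avg=1."""
        kw.setdefault("t_p", 200)
        kw.setdefault("n_opt", 5)
        kw.setdefault("n_step", 80)
        kw.setdefault("n_avg", 1)
        return ReconConfig(**kw)


@dataclass
class ReconResult:
    image: np.ndarray
    samples: List[np.ndarray]
    t_p: int
    diagnostics: dict = field(default_factory=dict)
    seeds: List[int] = field(default_factory=list)
    config: Optional[ReconConfig] = None


def _dc_residual(z0_hat: np.ndarray, y: MultiCoilKSpace, op: ForwardOperator,
                 codec: Codec):
    x = decode(z0_hat, codec)
    r = y.data - apply_forward(x, op).data
    return r, float(np.sum(np.abs(r) ** 2))


def dc_gradient_latent(zt: np.ndarray, t: int, y: MultiCoilKSpace,
                       op: ForwardOperator, codec: Codec, model: ScoreModel,
                       schedule: NoiseSchedule) -> np.ndarray:
    """Gradient w.r.t. z_t of ||y - A(D(E[z0|z_t]))||^2.

    The chain rule runs through Tweedie's formula (using the score model's
    input VJP) and the decoder; at t=0 the Tweedie map is the identity.
    """
    grad, _ = _dc_loss_grad(zt, t, y, op, codec, model, schedule)
    return grad


def _dc_loss_grad(zt, t, y, op, codec, model, schedule):
    if t >= 1:
        z0_hat = tweedie_denoise(zt, t, model, schedule)
    else:
        z0_hat = zt
    r, loss = _dc_residual(z0_hat, y, op, codec)
    g_img = -2.0 * apply_adjoint(MultiCoilKSpace(r, y.mask), op)
    u0 = decode_vjp(g_img, codec)
    if t >= 1:
        ab = schedule.alpha_bar[t]
        grad = (u0 - np.sqrt(1.0 - ab) * model.vjp(zt, t, u0)) / np.sqrt(ab)
    else:
        grad = u0
    return grad, loss


def ldps_sample(y: MultiCoilKSpace, op: ForwardOperator, z_start: np.ndarray,
                t_start: int, codec: Codec, model: ScoreModel,
                schedule: NoiseSchedule, config: ReconConfig,
                rng: Optional[np.random.Generator] = None,
                diagnostics: Optional[dict] = None) -> np.ndarray:
    """Hot-started LDPS: DDIM from t_start to 0 with n_opt DC updates per step.

    ``t_start`` is snapped to the nearest point of the DDIM grid; steps
    above it are skipped, so hot-starting also shortens sampling.
    """
    grid = ddim_grid(schedule, config.n_step)
    idx = int(np.argmin(np.abs(grid - t_start)))
    z = np.array(z_start, copy=True)
    traces = []
    for k in range(idx, 0, -1):
        t, t_next = int(grid[k]), int(grid[k - 1])
        z = ddim_step(z, t, t_next, model, schedule, eta=config.eta, rng=rng)
        if config.n_opt > 0:
            opt = Adam(z.shape, lr=config.lr)
            inner = []
            for _ in range(config.n_opt):
                g, loss = _dc_loss_grad(z, t_next, y, op, codec, model, schedule)
                inner.append(loss)
                z = opt.step(z, g)
            traces.append(inner)
    if diagnostics is not None:
        diagnostics["dc_residuals"] = traces
        diagnostics["grid"] = grid.tolist()
        diagnostics["t_start_snapped"] = int(grid[idx])
    return z


def output_dc(x_dec: np.ndarray, y: MultiCoilKSpace, op: ForwardOperator,
              lam_dc: float = 1e-2, n_cg: int = 6) -> np.ndarray:
    """Image-space data consistency: minimize ||Ax-y||^2 + lam ||x - x_dec||^2.

    Solved by n_cg conjugate-gradient iterations on the normal equations,
    started at the decoded image; the quadratic objective is non-increasing.
    """
    if n_cg < 1:
        raise ValueError("n_cg must be >= 1")
    b = apply_adjoint(y, op) + lam_dc * x_dec
    x = np.array(x_dec, copy=True)

    def normal(v):
        return apply_adjoint(apply_forward(v, op), op) + lam_dc * v

    r = b - normal(x)
    p = r.copy()
    rs = np.vdot(r, r).real
    for _ in range(n_cg):
        if rs < 1e-30:
            break
        Ap = normal(p)
        alpha = rs / np.vdot(p, Ap).real
        x = x + alpha * p
        r = r - alpha * Ap
        rs_new = np.vdot(r, r).real
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x


def average_samples(samples: Sequence[np.ndarray], mode: str = "complex") -> np.ndarray:
    if len(samples) == 0:
        raise ValueError("no samples to average")
    shapes = {s.shape for s in samples}
    if len(shapes) != 1:
        raise ValueError("samples must share a shape")
    if mode == "complex":
        return np.mean(samples, axis=0)
    if mode == "magnitude":
        return np.mean([np.abs(s) for s in samples], axis=0)
    raise ValueError(f"unknown averaging mode {mode!r}")


def hot_started_sample(y: MultiCoilKSpace, op: ForwardOperator, z0: np.ndarray,
                       t_p: int, codec: Codec, model: ScoreModel,
                       schedule: NoiseSchedule, config: ReconConfig,
                       sample_seed: Optional[int] = None,
                       diagnostics: Optional[dict] = None) -> np.ndarray:
    """One sample: project z0 to t_p, run LDPS down to 0, decode, output DC."""
    seed = config.seed if sample_seed is None else sample_seed
    rng = np.random.default_rng(seed)
    z_tp = forward_noise(z0, t_p, schedule, rng=rng)
    z = ldps_sample(y, op, z_tp, t_p, codec, model, schedule, config, rng=rng,
                    diagnostics=diagnostics)
    x = decode(z, codec)
    if config.n_cg_out > 0:
        x = output_dc(x, y, op, lam_dc=config.lam_dc, n_cg=config.n_cg_out)
    return x


def _run_samples(y, op, z0, t_p, codec, model, schedule, config):
    samples, seeds, diags = [], [], []
    for i in range(config.n_avg):
        seed = int(np.random.default_rng([config.seed, i]).integers(2 ** 31))
        d = {}
        samples.append(hot_started_sample(y, op, z0, t_p, codec, model,
                                          schedule, config, sample_seed=seed,
                                          diagnostics=d))
        seeds.append(seed)
        diags.append(d)
    image = average_samples(samples, config.avg_mode)
    return image, samples, seeds, diags


def caps_recon(y: MultiCoilKSpace, op: ForwardOperator, codec: Codec,
               model: ScoreModel, schedule: NoiseSchedule,
               config: Optional[ReconConfig] = None) -> ReconResult:
    """Prior-free reconstruction: CG-SENSE init, encode, project to fixed t_p."""
    config = config or ReconConfig.caps()
    t_p = 200 if config.t_p == "auto" else int(config.t_p)
    x_cg = cg_sense(y, op, lam=config.cg_lam, n_iter=config.cg_iter)
    z0 = encode(x_cg, codec)
    image, samples, seeds, diags = _run_samples(y, op, z0, t_p, codec, model,
                                                schedule, config)
    return ReconResult(image=image, samples=samples, t_p=t_p,
                       diagnostics={"per_sample": diags, "init": "cg_sense"},
                       seeds=seeds, config=config)


def laps_recon(y: MultiCoilKSpace, op: ForwardOperator, prior_mag: np.ndarray,
               codec: Codec, model: ScoreModel, schedule: NoiseSchedule,
               calib=None, config: Optional[ReconConfig] = None) -> ReconResult:
    """Longitudinal reconstruction hot-started from the prior scan.

    AutoInit supplies the initial phase, the registered prior, and the
    calibrated hot-start timestep (unless ``config.t_p`` is numeric).
    """
    from .hotstart import DEFAULT_CALIBRATION, auto_init
    if prior_mag is None:
        raise ValueError("no prior scan given; use caps_recon instead")
    config = config or ReconConfig()
    calib = calib or DEFAULT_CALIBRATION
    ai = auto_init(y, op, prior_mag, codec, model, schedule, calib,
                   seed=config.seed, register=config.register_prior)
    t_p = ai.t_p if config.t_p == "auto" else int(config.t_p)
    zP = encode(ai.prior_registered * np.exp(1j * ai.phase), codec)
    image, samples, seeds, diags = _run_samples(y, op, zP, t_p, codec, model,
                                                schedule, config)
    return ReconResult(image=image, samples=samples, t_p=t_p,
                       diagnostics={"per_sample": diags, "init": "prior",
                                    "tilde_tp": ai.tilde_tp,
                                    "transform": ai.transform},
                       seeds=seeds, config=config)
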