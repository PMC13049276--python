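"""Cartesian multi-coil MRI forward model and SENSE machinery.

Conventions (fixed so that k-space fixtures are bit-stable):

* FFTs are centered (half-shifted) and orthonormal with the negative-
  exponent forward transform: ``fft2c(x) = fftshift(fft2(ifftshift(x), norm='ortho'))``.
* Array index (0, 0) is the image corner; the k-space center sits at
  (N//2, M//2) after shifting.
* Coil sensitivities are normalized to unit root-sum-of-squares on their
  support, so ``A^H A`` equals the identity under full sampling.
* Noise is added at sampled k-space locations only (retrospective-
  undersampling semantics); unsampled entries are exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .masks import SamplingMask

__all__ = [
    "MultiCoilKSpace",
    "ForwardOperator",
    "fft2c",
    "ifft2c",
    "simulate_sensitivities",
    "estimate_sensitivities_lowres",
    "apply_forward",
    "apply_adjoint",
    "coil_compress",
    "cg_sense",
    "add_noise",
]


def fft2c(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"),
                           axes=(-2, -1))


def ifft2c(y: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(y, axes=(-2, -1)), norm="ortho"),
                           axes=(-2, -1))


@dataclass
class MultiCoilKSpace:
    """Per-coil k-space with its sampling mask and noise level (per real component)."""

    data: np.ndarray          # complex (n_coils, N, M)
    mask: SamplingMask
    sigma: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 3:
            raise ValueError("k-space must have shape (n_coils, N, M)")
        if self.data.shape[1:] != self.mask.shape:
            raise ValueError("k-space / mask shape mismatch")

    @property
    def n_coils(self):
        return self.data.shape[0]


@dataclass
class ForwardOperator:
    """A(x) = mask * F(s_c * x) per coil, with the FFT convention above."""

    smaps: np.ndarray         # complex (n_coils, N, M)
    mask: SamplingMask

    def __post_init__(self):
        self.smaps = np.asarray(self.smaps, dtype=np.complex128)
        if self.smaps.shape[1:] != self.mask.shape:
            raise ValueError("sensitivity / mask shape mismatch")

    @property
    def shape(self):
        return self.mask.shape


def simulate_sensitivities(n_coils: int, N: int, M: int, seed: int = 0,
                           lobe_width: float = 0.6) -> np.ndarray:
    """Smooth synthetic coil maps: Gaussian lobes on a ring, RSS-normalized.

    A stand-in for clinical head-coil arrays; the seed jitters lobe centers
    and widths slightly.
    """
    if n_coils < 1:
        raise ValueError("need at least one coil")
    if n_coils == 1:
        return np.ones((1, N, M), dtype=np.complex128)
    rng = np.random.default_rng(seed)
    yy = (np.arange(N) - N / 2) / (N / 2)
    xx = (np.arange(M) - M / 2) / (M / 2)
    Y, X = np.meshgrid(yy, xx, indexing="ij")
    maps = np.empty((n_coils, N, M), dtype=np.complex128)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.normal(0, 0.05)
        cy, cx = 1.1 * np.sin(ang), 1.1 * np.cos(ang)
        w = lobe_width * (1 + rng.normal(0, 0.05))
        mag = np.exp(-((Y - cy) ** 2 + (X - cx) ** 2) / (2 * w ** 2))
        # smooth linear+quadratic coil phase
        ph = rng.normal(0, 0.8) * (X * np.cos(ang) + Y * np.sin(ang)) \
            + rng.normal(0, 0.3) * (X ** 2 - Y ** 2)
        maps[c] = mag * np.exp(1j * ph)
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    return maps / rss


def estimate_sensitivities_lowres(y: MultiCoilKSpace, center_size: int = 24,
                                  support_frac: float = 0.1) -> np.ndarray:
    """Low-resolution sensitivity estimate from the fully sampled k-space center.

    The apodized central block is inverse-transformed per coil; maps are the
    low-pass coil images divided by their root-sum-of-squares, zeroed where
    the RSS falls below ``support_frac`` of its peak.  A documented surrogate
    for ESPIRiT calibration on the same region.
    """
    nc, N, M = y.data.shape
    cs = min(center_size, N, M)
    r0, c0 = N // 2 - cs // 2, M // 2 - cs // 2
    if not y.mask.mask[r0:r0 + cs, c0:c0 + cs].all():
        raise ValueError(f"central {cs}x{cs} region is not fully sampled")
    win = np.outer(np.hamming(cs), np.hamming(cs))
    klo = np.zeros_like(y.data)
    klo[:, r0:r0 + cs, c0:c0 + cs] = y.data[:, r0:r0 + cs, c0:c0 + cs] * win
    imgs = ifft2c(klo)
    rss = np.sqrt((np.abs(imgs) ** 2).sum(axis=0))
    support = rss > support_frac * rss.max()
    maps = np.zeros_like(imgs)
    maps[:, support] = imgs[:, support] / rss[support]
    return maps


def apply_forward(x: np.ndarray, op: ForwardOperator) -> MultiCoilKSpace:
    x = np.asarray(x, dtype=np.complex128)
    if x.shape != op.shape:
        raise ValueError(f"image shape {x.shape} does not match operator {op.shape}")
    y = fft2c(op.smaps * x[None]) * op.mask.mask[None]
    return MultiCoilKSpace(y, op.mask, 0.0)


def apply_adjoint(y: MultiCoilKSpace, op: ForwardOperator) -> np.ndarray:
    if y.data.shape != op.smaps.shape:
        raise ValueError("k-space / operator shape mismatch")
    imgs = ifft2c(y.data * op.mask.mask[None])
    return (np.conj(op.smaps) * imgs).sum(axis=0)


def _normal_op(x: np.ndarray, op: ForwardOperator, lam: float) -> np.ndarray:
    return apply_adjoint(apply_forward(x, op), op) + lam * x


def coil_compress(y: MultiCoilKSpace, energy: float = 0.95
                  ) -> Tuple[MultiCoilKSpace, np.ndarray]:
    """SVD coil compression retaining the given fraction of squared-singular-value energy.

    Returns the compressed k-space and the (n_virtual, n_coils) projection
    matrix; apply it to sensitivity maps with ``P @ maps.reshape(nc, -1)``.
    """
    if not (0 < energy <= 1):
        raise ValueError("energy must lie in (0, 1]")
    nc, N, M = y.data.shape
    samp = y.mask.mask
    Ymat = y.data[:, samp]                     # (nc, n_samples)
    U, s, _ = np.linalg.svd(Ymat, full_matrices=False)
    frac = np.cumsum(s ** 2) / max(np.sum(s ** 2), 1e-30)
    k = int(np.searchsorted(frac, energy - 1e-12) + 1)
    P = U[:, :k].conj().T                      # (k, nc)
    comp = (P @ y.data.reshape(nc, -1)).reshape(k, N, M)
    comp[:, ~samp] = 0.0
    return MultiCoilKSpace(comp, y.mask, y.sigma), P


def cg_sense(y: MultiCoilKSpace, op: ForwardOperator, lam: float = 0.0,
             n_iter: int = 10) -> np.ndarray:
    """Conjugate gradients on (A^H A + lam I) x = A^H y, started from zero."""
    if lam < 0 or n_iter < 1:
        raise ValueError("require lam >= 0 and n_iter >= 1")
    b = apply_adjoint(y, op)
    x = np.zeros_like(b)
    r = b.copy()
    p = r.copy()
    rs = np.vdot(r, r).real
    for _ in range(n_iter):
        if rs < 1e-30:
            break
        Ap = _normal_op(p, op, lam)
        alpha = rs / np.vdot(p, Ap).real
        x = x + alpha * p
        r = r - alpha * Ap
        rs_new = np.vdot(r, r).real
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x


def add_noise(y: MultiCoilKSpace, sigma: float, seed: int = 0) -> MultiCoilKSpace:
    """Add i.i.d. complex Gaussian noise (sigma per real component) at sampled points."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return MultiCoilKSpace(y.data.copy(), y.mask, y.sigma)
    rng = np.random.default_rng(seed)
    noise = sigma * (rng.standard_normal(y.data.shape)
                     + 1j * rng.standard_normal(y.data.shape))
    data = y.data + noise * y.mask.mask[None]
    return MultiCoilKSpace(data, y.mask, float(np.hypot(y.sigma, sigma)))
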