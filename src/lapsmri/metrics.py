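"""Reconstruction quality metrics.

PSNR and SSIM are computed on magnitudes, with the reference peak as the
dynamic range.  The patch analysis divides the image into 32x32 patches
with 50% overlap, scores each patch by cosine similarity between the
reference and the prior scan, bins patches by similarity percentile
(top 10%, 10-50%, 50-90%, bottom 10%), and reports per-bin mean PSNR/SSIM
for each reconstruction and for the prior-vs-target baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["PatchMetricReport", "psnr", "ssim", "patch_similarity_analysis",
           "evaluate_volume"]

PSNR_CAP = 100.0


def _mag(x):
    return np.abs(np.asarray(x))


def psnr(ref: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB on magnitudes; peak = max |ref|."""
    ref_m, test_m = _mag(ref), _mag(test)
    if ref_m.shape != test_m.shape:
        raise ValueError(f"shape mismatch {ref_m.shape} vs {test_m.shape}")
    peak = ref_m.max()
    rmse = np.sqrt(np.mean((ref_m - test_m) ** 2))
    if rmse == 0 or peak == 0:
        return PSNR_CAP
    return float(min(20.0 * np.log10(peak / rmse), PSNR_CAP))


def ssim(ref: np.ndarray, test: np.ndarray, win_size: int = 7) -> float:
    """Mean SSIM on magnitudes normalized by the reference peak.

    Gaussian-weighted 7x7 window with the standard constants (K1=0.01,
    K2=0.03).
    """
    ref_m, test_m = _mag(ref), _mag(test)
    if ref_m.shape != test_m.shape:
        raise ValueError(f"shape mismatch {ref_m.shape} vs {test_m.shape}")
    peak = ref_m.max() or 1.0
    return float(structural_similarity(ref_m / peak, test_m / peak,
                                       data_range=1.0, gaussian_weights=True,
                                       win_size=win_size, sigma=1.5,
                                       use_sample_covariance=False))


@dataclass
class PatchMetricReport:
    patch: int
    overlap: float
    similarities: np.ndarray                 # per-patch cosine similarity
    bin_edges_pct: Sequence[float]           # percentile edges, most->least similar
    bin_counts: np.ndarray
    per_bin: Dict[str, dict] = field(default_factory=dict)
    # per_bin[method] = {"psnr": [...], "ssim": [...]} per bin


def _patch_grid(shape, patch, stride):
    N, M = shape
    rows = range(0, N - patch + 1, stride)
    cols = range(0, M - patch + 1, stride)
    return [(r, c) for r in rows for c in cols]


def patch_similarity_analysis(ref: np.ndarray, prior: np.ndarray,
                              recons: Dict[str, np.ndarray],
                              patch: int = 32, overlap: float = 0.5
                              ) -> PatchMetricReport:
    """Similarity-binned local metric report; see module docstring."""
    ref_m = _mag(ref)
    prior_m = _mag(prior)
    N, M = ref_m.shape
    if N < patch or M < patch:
        raise ValueError(f"image {ref_m.shape} smaller than patch size {patch}")
    stride = max(int(round(patch * (1.0 - overlap))), 1)
    grid = _patch_grid((N, M), patch, stride)

    def patches(img):
        return np.stack([img[r:r + patch, c:c + patch].ravel() for r, c in grid])

    P_ref = patches(ref_m)
    P_pri = patches(prior_m)
    num = (P_ref * P_pri).sum(axis=1)
    den = np.linalg.norm(P_ref, axis=1) * np.linalg.norm(P_pri, axis=1)
    sims = np.where(den > 0, num / np.maximum(den, 1e-30), 0.0)

    # rank by similarity, most similar first; stable ranking handles ties
    order = np.argsort(-sims, kind="stable")
    n = len(sims)
    edges_pct = (0.0, 10.0, 50.0, 90.0, 100.0)
    bounds = [int(round(p / 100.0 * n)) for p in edges_pct]
    bins = [order[bounds[i]:bounds[i + 1]] for i in range(4)]
    counts = np.array([len(b) for b in bins])

    methods = dict(recons)
    methods["prior"] = prior
    per_bin = {}
    for name, img in methods.items():
        img_m = _mag(img)
        if img_m.shape != ref_m.shape:
            raise ValueError(f"reconstruction {name!r} shape mismatch")
        ps, ss = [], []
        for b in bins:
            vals_p, vals_s = [], []
            for idx in b:
                r, c = grid[idx]
                pr = ref_m[r:r + patch, c:c + patch]
                pt = img_m[r:r + patch, c:c + patch]
                vals_p.append(psnr(pr, pt))
                if patch >= 7:
                    vals_s.append(ssim(pr, pt))
            ps.append(float(np.mean(vals_p)) if vals_p else np.nan)
            ss.append(float(np.mean(vals_s)) if vals_s else np.nan)
        per_bin[name] = {"psnr": ps, "ssim": ss}

    return PatchMetricReport(patch=patch, overlap=overlap, similarities=sims,
                             bin_edges_pct=edges_pct, bin_counts=counts,
                             per_bin=per_bin)


def evaluate_volume(slices: Sequence[dict], methods: Sequence[str],
                    n_eval_slices: int = 15) -> dict:
    """Aggregate per-method PSNR/SSIM over evenly spaced slices of a volume.

    ``slices`` is a list of dicts with keys "ref" and one entry per method.
    Returns {"indices": [...], method: {"psnr_mean": .., "psnr_sd": ..,
    "ssim_mean": .., "ssim_sd": ..}}.
    """
    n = len(slices)
    if n == 0:
        raise ValueError("no slices")
    if n < n_eval_slices:
        warnings.warn(f"only {n} slices available; using all")
        idx = np.arange(n)
    else:
        idx = np.round(np.linspace(0, n - 1, n_eval_slices)).astype(int)
    out = {"indices": idx.tolist()}
    for m in methods:
        ps = [psnr(slices[i]["ref"], slices[i][m]) for i in idx]
        ss = [ssim(slices[i]["ref"], slices[i][m]) for i in idx]
        out[m] = {"psnr_mean": float(np.mean(ps)), "psnr_sd": float(np.std(ps)),
                  "ssim_mean": float(np.mean(ss)), "ssim_sd": float(np.std(ss))}
    return out
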