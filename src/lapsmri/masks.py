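"""Variable-density Cartesian undersampling masks.

1D masks select whole phase-encode lines (constant along the readout
dimension, axis 0); 2D masks select individual k-space points.  Both keep a
fully sampled center block, counted in the reported acceleration R, and
draw the remaining samples without replacement with probability
proportional to (1 + |k|)^(-density_exponent).  Among ``n_resample`` seeded
candidate draws, the mask minimizing the largest gap (largest distance
between adjacent sampled lines in 1D, largest empty-disc radius in 2D) is
returned — an iterative re-sampling scheme that suppresses large holes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SamplingMask",
    "make_vd_mask_1d",
    "make_vd_mask_2d",
    "subsample_within_acquired",
    "max_gap_1d",
    "max_gap_2d",
]


@dataclass
class SamplingMask:
    mask: np.ndarray          # bool (N, M)
    kind: str                 # "1d" or "2d"
    center: int               # center lines (1d) or center block side (2d)
    R_nominal: float
    R_achieved: float = field(default=0.0)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        n_ones = int(self.mask.sum())
        self.R_achieved = self.mask.size / max(n_ones, 1)

    @property
    def shape(self):
        return self.mask.shape


def _center_cols(M: int, width: int) -> np.ndarray:
    lo = M // 2 - width // 2
    return np.arange(lo, lo + width)


def max_gap_1d(cols: np.ndarray, M: int) -> int:
    """Largest spacing between adjacent sampled columns (edges included)."""
    cols = np.sort(cols)
    ext = np.concatenate([[-1], cols, [M]])
    return int(np.diff(ext).max())


def max_gap_2d(mask: np.ndarray) -> float:
    """Largest empty-disc radius on the sampled lattice."""
    return float(ndimage.distance_transform_edt(~mask).max())


def make_vd_mask_1d(N: int, M: int, R: float, center_lines: int = 24,
                    density_exponent: float = 2.0, n_resample: int = 30,
                    seed: int = 0) -> SamplingMask:
    if R < 1:
        raise ValueError("R must be >= 1")
    if center_lines < 2:
        raise ValueError("need at least 2 center lines")
    n_lines = int(round(M / R))
    center = _center_cols(M, min(center_lines, M))
    if R <= 1.0:
        return SamplingMask(np.ones((N, M), dtype=bool), "1d", len(center), R)
    if n_lines < len(center):
        raise ValueError(f"center ({len(center)} lines) exceeds the sampling "
                         f"budget ({n_lines} lines) at R={R}")
    k = np.arange(M) - M // 2
    p = (1.0 + np.abs(k)) ** (-density_exponent)
    p[center] = 0.0
    p /= p.sum()
    cand_pool = np.flatnonzero(p > 0)
    n_extra = n_lines - len(center)

    best, best_gap = None, np.inf
    for i in range(n_resample):
        rng = np.random.default_rng([seed, i])
        extra = rng.choice(M, size=n_extra, replace=False, p=p)
        cols = np.concatenate([center, extra])
        gap = max_gap_1d(cols, M)
        if gap < best_gap:
            best, best_gap = cols, gap
    mask = np.zeros((N, M), dtype=bool)
    mask[:, best] = True
    return SamplingMask(mask, "1d", len(center), R)


def make_vd_mask_2d(N: int, M: int, R: float, center_block: int = 24,
                    density_exponent: float = 2.0, n_resample: int = 30,
                    seed: int = 0) -> SamplingMask:
    if R < 1:
        raise ValueError("R must be >= 1")
    n_pts = int(round(N * M / R))
    cb = min(center_block, N, M)
    cmask = np.zeros((N, M), dtype=bool)
    cmask[N // 2 - cb // 2:N // 2 - cb // 2 + cb,
          M // 2 - cb // 2:M // 2 - cb // 2 + cb] = True
    if R <= 1.0:
        return SamplingMask(np.ones((N, M), dtype=bool), "2d", cb, R)
    n_center = int(cmask.sum())
    if n_pts < n_center:
        raise ValueError(f"center block ({n_center} points) exceeds the "
                         f"sampling budget ({n_pts} points) at R={R}")
    ky = np.arange(N) - N // 2
    kx = np.arange(M) - M // 2
    kr = np.hypot(ky[:, None], kx[None, :])
    p = (1.0 + kr) ** (-density_exponent)
    p[cmask] = 0.0
    p = (p / p.sum()).ravel()
    n_extra = n_pts - n_center

    best, best_gap = None, np.inf
    for i in range(n_resample):
        rng = np.random.default_rng([seed, i])
        extra = rng.choice(N * M, size=n_extra, replace=False, p=p)
        mask = cmask.copy()
        mask.ravel()[extra] = True
        gap = max_gap_2d(mask)
        if gap < best_gap:
            best, best_gap = mask, gap
    return SamplingMask(best, "2d", cb, R)


def subsample_within_acquired(existing: SamplingMask, R_target: float,
                              density_exponent: float = 2.0, n_resample: int = 30,
                              seed: int = 0) -> SamplingMask:
    """Retrospectively increase R by drawing only from already-acquired samples."""
    if R_target < existing.R_achieved - 1e-9:
        raise ValueError(f"target R={R_target} below achieved R={existing.R_achieved:.2f}")
    N, M = existing.shape
    if abs(R_target - existing.R_achieved) < 1e-9:
        return SamplingMask(existing.mask.copy(), existing.kind, existing.center,
                            R_target)
    if existing.kind == "1d":
        acquired = np.flatnonzero(existing.mask.any(axis=0))
        center = _center_cols(M, existing.center)
        n_lines = int(round(M / R_target))
        if n_lines < len(center):
            raise ValueError("center exceeds budget at target R")
        pool = np.setdiff1d(acquired, center)
        k = pool - M // 2
        p = (1.0 + np.abs(k)) ** (-density_exponent)
        p /= p.sum()
        n_extra = min(n_lines - len(center), len(pool))
        best, best_gap = None, np.inf
        for i in range(n_resample):
            rng = np.random.default_rng([seed, i])
            extra = rng.choice(pool, size=n_extra, replace=False, p=p)
            cols = np.concatenate([center, extra])
            gap = max_gap_1d(cols, M)
            if gap < best_gap:
                best, best_gap = cols, gap
        mask = np.zeros((N, M), dtype=bool)
        mask[:, best] = True
        out = SamplingMask(mask, "1d", existing.center, R_target)
    else:
        cb = existing.center
        cmask = np.zeros((N, M), dtype=bool)
        cmask[N // 2 - cb // 2:N // 2 - cb // 2 + cb,
              M // 2 - cb // 2:M // 2 - cb // 2 + cb] = True
        cmask &= existing.mask
        pool = np.flatnonzero(existing.mask.ravel() & ~cmask.ravel())
        n_pts = int(round(N * M / R_target))
        n_extra = min(max(n_pts - int(cmask.sum()), 0), len(pool))
        ky = np.arange(N) - N // 2
        kx = np.arange(M) - M // 2
        kr = np.hypot(ky[:, None], kx[None, :]).ravel()[pool]
        p = (1.0 + kr) ** (-density_exponent)
        p /= p.sum()
        best, best_gap = None, np.inf
        for i in range(n_resample):
            rng = np.random.default_rng([seed, i])
            extra = rng.choice(pool, size=n_extra, replace=False, p=p)
            mask = cmask.copy()
            mask.ravel()[extra] = True
            gap = max_gap_2d(mask)
            if gap < best_gap:
                best, best_gap = mask, gap
        out = SamplingMask(best, "2d", cb, R_target)
    assert np.all(existing.mask[out.mask]), "subsample left the acquired set"
    return out
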