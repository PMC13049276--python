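"""Synthetic longitudinal phantom pairs.

Emulates the clinical longitudinal data model: a prior-session magnitude
image and a follow-up scan that differs by controlled anatomical change
(lesions, cavities, smooth deformation, contrast drift), possible rigid
misregistration of the prior, smooth quadratic receive phase on the
follow-up, smooth multi-coil sensitivities, additive complex Gaussian
noise, and retrospective variable-density undersampling with a fully
sampled center.

Change presets map qualitative change grades to expected changed-pixel
fractions: low ~1%, med ~5%, high ~15%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .codec import synth_phase_augment
from .masks import make_vd_mask_1d, make_vd_mask_2d
from .operators import MultiCoilKSpace, ForwardOperator, add_noise, apply_forward, \
    simulate_sensitivities

__all__ = [
    "ChangeSpec",
    "LongitudinalPair",
    "make_phantom",
    "apply_changes",
    "misregister",
    "make_pair",
]


@dataclass
class ChangeSpec:
    """List of change operations applied to the follow-up image.

    Each op is a (name, kwargs) tuple; supported names: ``add_lesion``
    (center frac-coords, radius px, delta), ``carve_cavity`` (center,
    radius, depth), ``smooth_deformation`` (amplitude px, scale px),
    ``global_contrast`` (scale).
    """

    ops: Sequence[Tuple[str, dict]] = field(default_factory=list)
    level: str = "custom"

    @staticmethod
    def preset(level: str, N: int = 64, seed: int = 0) -> "ChangeSpec":
        level_id = {"none": 0, "low": 1, "med": 2, "high": 3}.get(level, 99)
        rng = np.random.default_rng([seed, level_id])
        if level == "none":
            return ChangeSpec([], "none")

        def lesion(radius_frac, delta):
            c = tuple(rng.uniform(0.3, 0.7, size=2))
            return ("add_lesion", {"center": c, "radius": radius_frac * N,
                                   "delta": delta})
        if level == "low":
            ops = [lesion(0.055, 0.35)]
        elif level == "med":
            ops = [lesion(0.09, 0.4), ("carve_cavity", {
                "center": tuple(rng.uniform(0.35, 0.65, size=2)),
                "radius": 0.07 * N, "depth": 0.5})]
        elif level == "high":
            ops = [lesion(0.12, 0.45),
                   ("carve_cavity", {"center": tuple(rng.uniform(0.35, 0.65, size=2)),
                                     "radius": 0.10 * N, "depth": 0.6}),
                   ("smooth_deformation", {"amplitude": 0.02 * N, "scale": 0.25 * N}),
                   ("global_contrast", {"scale": 1.06})]
        else:
            raise ValueError(f"unknown change preset {level!r}")
        return ChangeSpec(ops, level)


@dataclass
class LongitudinalPair:
    prior_mag: np.ndarray          # real (N, M), possibly misregistered
    followup: np.ndarray           # complex (N, M)
    kspace: MultiCoilKSpace
    change_map: np.ndarray         # bool (N, M)
    smaps: np.ndarray
    misreg: dict
    meta: dict = field(default_factory=dict)


def make_phantom(N: int, M: int, seed: int = 0, complexity: float = 1.0) -> np.ndarray:
    """Random smooth ellipse/blob composition with mild texture, values in [0, 1]."""
    rng = np.random.default_rng(seed)
    yy = (np.arange(N) - N / 2) / (N / 2)
    xx = (np.arange(M) - M / 2) / (M / 2)
    Y, X = np.meshgrid(yy, xx, indexing="ij")

    def ellipse(cy, cx, ry, rx, theta, soft=0.15):
        Yr = (Y - cy) * np.cos(theta) + (X - cx) * np.sin(theta)
        Xr = -(Y - cy) * np.sin(theta) + (X - cx) * np.cos(theta)
        r = (Yr / ry) ** 2 + (Xr / rx) ** 2
        return expit((1.0 - r) / soft)

    head = ellipse(rng.uniform(-0.08, 0.08), rng.uniform(-0.08, 0.08),
                   rng.uniform(0.6, 0.9), rng.uniform(0.55, 0.82),
                   rng.uniform(-0.4, 0.4))
    img = rng.uniform(0.35, 0.6) * head
    n_blobs = int(round(complexity * rng.integers(6, 12)))
    for _ in range(n_blobs):
        cy, cx = rng.uniform(-0.55, 0.55, size=2)
        ry, rx = rng.uniform(0.07, 0.4, size=2)
        amp = rng.uniform(-0.45, 0.55)
        img += amp * ellipse(cy, cx, ry, rx, rng.uniform(0, np.pi)) * head
    # smooth texture confined to the head
    tex = ndimage.gaussian_filter(rng.standard_normal((N, M)), sigma=2.0)
    tex /= max(np.abs(tex).max(), 1e-12)
    img += 0.06 * complexity * tex * head
    img = np.clip(img, 0.0, None)
    return img / max(img.max(), 1e-12)


def _disc(N, M, center, radius, taper=2.0):
    # compactly supported: 1 inside radius-taper, cosine falloff, 0 outside radius
    cy, cx = center[0] * N, center[1] * M
    Y, X = np.meshgrid(np.arange(N), np.arange(M), indexing="ij")
    r = np.hypot(Y - cy, X - cx)
    u = np.clip((radius - r) / max(taper, 1e-6), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * u))


def apply_changes(image: np.ndarray, spec: ChangeSpec, seed: int = 0
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Apply the listed change operations; returns (changed image, change map)."""
    img = np.asarray(image, dtype=np.float64).copy()
    N, M = img.shape
    rng = np.random.default_rng(seed)
    for name, kw in spec.ops:
        if name == "add_lesion":
            cy, cx = kw["center"]
            if not (0 <= cy <= 1 and 0 <= cx <= 1):
                raise ValueError(f"lesion center {kw['center']} outside the image")
            img += kw["delta"] * _disc(N, M, kw["center"], kw["radius"])
        elif name == "carve_cavity":
            cy, cx = kw["center"]
            if not (0 <= cy <= 1 and 0 <= cx <= 1):
                raise ValueError(f"cavity center {kw['center']} outside the image")
            img *= 1.0 - kw["depth"] * _disc(N, M, kw["center"], kw["radius"])
        elif name == "smooth_deformation":
            amp, scale = kw["amplitude"], kw["scale"]
            dy = ndimage.gaussian_filter(rng.standard_normal((N, M)), scale)
            dx = ndimage.gaussian_filter(rng.standard_normal((N, M)), scale)
            for d in (dy, dx):
                d *= amp / max(np.abs(d).max(), 1e-12)
            Y, X = np.meshgrid(np.arange(N), np.arange(M), indexing="ij")
            img = ndimage.map_coordinates(img, [Y + dy, X + dx], order=1,
                                          mode="nearest")
        elif name == "global_contrast":
            img = np.clip(img * kw["scale"], 0.0, None)
        else:
            raise ValueError(f"unknown change op {name!r}")
    img = np.clip(img, 0.0, None)
    change_map = np.abs(img - image) > 1e-3
    return img, change_map


def misregister(image: np.ndarray, rotation_deg: float = 0.0,
                translation_px: Tuple[float, float] = (0.0, 0.0),
                surrogate_slice_offset: float = 0.0,
                seed: int = 0) -> np.ndarray:
    """Rigidly perturb an image; optionally blend toward a correlated surrogate.

    The surrogate-slice blend mimics selecting a prior slice off the target
    plane: the image is mixed with a strongly deformed copy of itself, so
    correlation degrades monotonically with the offset in [0, 1].
    """
    img = np.asarray(image, dtype=np.float64)
    out = img
    if surrogate_slice_offset > 0:
        w = float(np.clip(surrogate_slice_offset, 0.0, 1.0))
        alt, _ = apply_changes(img, ChangeSpec([
            ("smooth_deformation", {"amplitude": 0.12 * img.shape[0],
                                    "scale": 0.2 * img.shape[0]})]), seed=seed + 7)
        out = (1 - 0.6 * w) * out + 0.6 * w * alt
    if rotation_deg != 0.0:
        out = ndimage.rotate(out, rotation_deg, reshape=False, order=5,
                             mode="constant", cval=0.0)
    if translation_px != (0.0, 0.0):
        out = ndimage.shift(out, translation_px, order=5, mode="constant", cval=0.0)
    return np.clip(out, 0.0, None)


def make_pair(seed: int = 0, N: int = 64, M: Optional[int] = None,
              change_level: str = "low",
              misreg: Optional[dict] = None,
              phase_seed: Optional[int] = None,
              n_coils: int = 8, sigma: float = 0.0,
              mask_spec: Optional[dict] = None) -> LongitudinalPair:
    """Generate one longitudinal pair end to end.

    ``mask_spec`` like {"kind": "1d", "R": 6, "center": 16}; defaults to 1D
    R=6.  With no change, no misregistration, zero phase seed variation and
    sigma=0, the prior equals the follow-up magnitude exactly and the stored
    k-space equals the forward model of the follow-up.
    """
    M = M or N
    misreg = dict(misreg or {})
    mask_spec = dict(mask_spec or {"kind": "1d", "R": 6.0})
    base = make_phantom(N, M, seed=seed)

    spec = ChangeSpec.preset(change_level, N=N, seed=seed)
    followup_mag, change_map = apply_changes(base, spec, seed=seed + 1)
    followup = synth_phase_augment(followup_mag, seed=phase_seed if phase_seed is not None
                                   else seed + 2)

    prior = misregister(base, misreg.get("rotation_deg", 0.0),
                        tuple(misreg.get("translation_px", (0.0, 0.0))),
                        misreg.get("surrogate_slice_offset", 0.0), seed=seed)

    center = mask_spec.get("center")
    if center is None:
        center = max(4, int(round(24 * M / 256)))
        if mask_spec["kind"] == "1d":
            center = max(2, min(center, int(round(M / mask_spec["R"])) - 2))
    if mask_spec["kind"] == "1d":
        mask = make_vd_mask_1d(N, M, mask_spec["R"], center_lines=center,
                               seed=seed + 3)
    else:
        mask = make_vd_mask_2d(N, M, mask_spec["R"], center_block=center,
                               seed=seed + 3)
    smaps = simulate_sensitivities(n_coils, N, M, seed=seed + 4)
    op = ForwardOperator(smaps, mask)
    y = apply_forward(followup, op)
    y = add_noise(y, sigma, seed=seed + 5)
    return LongitudinalPair(
        prior_mag=prior, followup=followup, kspace=y, change_map=change_map,
        smaps=smaps, misreg=misreg,
        meta={"seed": seed, "change_level": change_level, "sigma": sigma,
              "mask_spec": mask_spec, "n_coils": n_coils})
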