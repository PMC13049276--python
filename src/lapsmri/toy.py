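"""Desk-scale study conditions: toy trained models and longitudinal pairs.

One fixed recipe — 64x64 phantoms, a K=4/C=4 codec, and a width-48 score
network trained on 400 flip-augmented latents — is shared by the test
suite and the acceptance experiments so every ordering is measured under
the same conditions.
"""

from __future__ import annotations

from .codec import encode, synth_phase_augment, train_codec
from .phantom import make_pair, make_phantom
from .schedule import make_schedule, train_score_model

__all__ = ["toy_corpus", "train_toy_models", "study_pair"]

STUDY_N = 64
STUDY_COILS = 8
STUDY_SIGMA = 0.005      # per real component; ~30 dB measurement SNR
STUDY_MASK = {"kind": "1d", "R": 6.0, "center": 8}


def toy_corpus(n_phantoms: int = 200, N: int = STUDY_N, seed: int = 0):
    """Flip-augmented complex phantom corpus for codec/score training."""
    base = [make_phantom(N, N, seed=seed * 100_000 + s) for s in range(n_phantoms)]
    aug = base + [b[:, ::-1].copy() for b in base]
    return [synth_phase_augment(m, seed=20_000 + 7 * seed + i)
            for i, m in enumerate(aug)]


def train_toy_models(seed: int = 0, n_phantoms: int = 200, epochs: int = 50,
                     width: int = 48):
    """Train the study codec and score model; returns (codec, model, schedule)."""
    imgs = toy_corpus(n_phantoms, seed=seed)
    codec = train_codec(imgs[:n_phantoms], K=4, C=4, seed=seed)
    schedule = make_schedule(1000)
    latents = [encode(x, codec) for x in imgs]
    model = train_score_model(latents, schedule, epochs=epochs, seed=seed,
                              width=width, lr=2e-3, batch_size=64)
    return codec, model, schedule


def study_pair(seed: int, change: str = "low", misreg=None,
               unrelated_prior: bool = False, N: int = STUDY_N,
               mask_spec=None):
    """One longitudinal pair under the study conditions.

    ``unrelated_prior=True`` replaces the prior with a different subject's
    phantom (the dissimilar-prior condition).
    """
    p = make_pair(seed=seed, N=N, change_level=change, misreg=misreg,
                  n_coils=STUDY_COILS, sigma=STUDY_SIGMA,
                  mask_spec=dict(mask_spec or STUDY_MASK))
    if unrelated_prior:
        p.prior_mag = make_phantom(N, N, seed=seed + 50_000)
        p.meta["unrelated_prior"] = True
    return p
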