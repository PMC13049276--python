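# Methods

`lapsmri` reconstructs undersampled multi-coil Cartesian MRI by posterior
sampling with a latent diffusion prior, optionally *hot-started* from the
subject's previous scan. This note records the model, the numerical
choices, and what the desk-scale experiments do and do not demonstrate.

## Forward model

A slice `x ∈ C^{N×M}` is observed through `y = M F S x + n`: coil
sensitivity weighting `S` (maps normalized to unit root-sum-of-squares on
their support), a centered orthonormal 2-D FFT `F` (negative-exponent
forward, k-space center at `(N//2, M//2)`), a binary sampling mask `M`,
and i.i.d. complex Gaussian noise (σ per real component, added at sampled
locations only — retrospective-undersampling semantics). With this
normalization `AᴴA = I` under full sampling, so operator tests have exact
expectations. ESPIRiT calibration is replaced by a low-resolution
surrogate: apodized central k-space, per-coil low-pass images divided by
their root-sum-of-squares, zeroed off support. The interface accepts
externally computed maps so a full ESPIRiT could be slotted in.

Variable-density masks draw phase-encode lines (1-D) or points (2-D)
without replacement with probability ∝ `(1+|k|)^(−q)` (`q=2` by default)
around an always-sampled center (24 lines / 24×24 at 256 resolution,
scaled down proportionally at fixture sizes). Among `n_resample=30` seeded
candidate draws the mask minimizing the largest gap — inter-line spacing
in 1-D, largest empty-disc radius in 2-D — is kept. The fully sampled
center counts toward the reported acceleration `R = N·M / #samples`.

## Latent codec

The encoder projects each `K×K×2` real/imaginary patch onto its top `C`
principal components (`K=4`, `C=4`: a 256×256 complex image becomes a
64×64×4 real latent). The decoder reconstructs each patch *from the 3×3
neighborhood of latent vectors* by a ridge-fit linear map, so spatial
context recovers the within-patch gradients the per-patch projection
discards. Both maps are linear: the decoder's vector-Jacobian product is
exact and cheap, which the data-consistency gradient relies on. This is a
deliberate departure from a trained VAE backbone: it is the L2-optimal
linear autoencoder, it is deterministic at inference (the reference
pipeline also samples nothing from its VAE at reconstruction time), and it
trains in seconds on one CPU. The cost is a lossier bottleneck at small
image sizes — held-out round-trip NRMSE is ≈0.07 on 64×64 phantoms but
≈0.02 at 128×128 and ≈0.01 at 256×256, where a K=4 compression is actually
intended to operate. Output data consistency is the designated corrector
for decoder loss. Latents are divided by a global scale estimated from the
training corpus (stored on the codec) so diffusion training sees
approximately unit-variance inputs. An exact identity codec (`K=1`,
`C=2`, channels = real/imag) makes every latent-space operation testable
against its image-space counterpart.

Magnitude-only prior images are made complex by a random quadratic phase
`φ(u,v) = a u² + b u v + c v² + d u + e v + f` on `[−1,1]²` coordinates
with coefficients uniform in `[−π, π]` (total excursion ≲ 4π), emulating
smooth receive phase; the modulus is preserved exactly.

## Diffusion machinery

A discrete variance-preserving process with `T=1000` steps and linear β
from 1e-4 to 0.02 (the common DDPM choice; the cumulative factor
ᾱ_T ≈ 4·10⁻⁵). Models follow the ε-prediction convention; the denoised
posterior mean comes from Tweedie's formula
`E[z0|z_t] = (z_t − √(1−ᾱ_t) ε̂)/√ᾱ_t`. Sampling uses DDIM on a uniform
sub-grid (`n_step=100` by default, deterministic at η=0); ancestral DDPM
stepping exists for cross-checks. Analytic score oracles for diagonal
Gaussian priors make the sampler testable against closed forms: for
`z0 ~ N(0,I)` the exact prediction is `ε̂ = √(1−ᾱ_t)·z_t`, and 50-step
deterministic DDIM reproduces the prior to within a ≈4% covariance
contraction (the discretization bias of the finite grid), which the
acceptance test bounds at 10%.

The trained score network is a small conditioned CNN written directly on
numpy with explicit forward/backward passes (width 48, depth 2). The
timestep enters twice: a sinusoidal embedding is projected to per-channel
FiLM scale/shift before each activation, and a t-gained linear skip runs
from the input to the near-zero-initialized output head — the score of
any Gaussian component is linear in z with a t-dependent gain, so these
two paths matter (additive-only conditioning cannot even represent the
optimal predictor for Gaussian data). Training is denoising score
matching with Adam, seed-deterministic, with a fixed-noise validation
split. The same backward machinery supplies the input-side
vector-Jacobian product that the data-consistency gradient needs; all
passes are finite-difference checked in the tests.

## Hot-start selection (TimeProject)

Projecting the prior latent to timestep t,
`z_t^P = √ᾱ_t z_P + √(1−ᾱ_t) ε`, and assuming a standard-Gaussian latent
population, the likelihood of a reference latent given that
initialization, marginalized over ε, is Gaussian:

    z_ref | project(z_P, t)  ~  N( ᾱ_t z_P, (1 − ᾱ_t²) I )

so the objective is

    J(t) = d·γ_t − ‖z_ref − ᾱ_t z_P‖² / (2(1 − ᾱ_t²)) − (d/2)·log 2π,
    γ_t = −½ log(1 − ᾱ_t²).

This closed form was re-derived here and is verified in the tests against
an importance-sampled Monte-Carlo marginalization oracle (agreement within
0.02 after max-normalization; the oracle is unbiased for any proposal, so
it does not depend on the closed form under test). `J` trades a
sharpening normalizer (favoring small t when latents agree) against the
discrepancy term (pushing t toward T as `‖z_ref − z_P‖` grows) and is
unimodal on the grid; ties break toward smaller t (maximal prior
reliance). At inference the unknown target latent is replaced by the
encoded fast preliminary reconstruction, and the resulting proxy t̃_p is
mapped through an affine calibration `t_p = v_p t̃_p + w_p`, clipped to
`[t_min, T]` with `t_min = 50` (never start below one DDIM step's worth of
noise). The clinical-scale constants `v_p=1.55, w_p=−350` ship as
defaults; desk-scale studies fit their own constants because phantom
latents occupy a much narrower similarity range than clinical latents
(unrelated phantom pairs sit at `‖Δz‖²/d ≈ 0.36`, far from the `≈2` of
independent Gaussian draws, so the proxy compresses toward small values).

Calibration runs the hot-started sampler over a t_p grid per validation
pair — with the same reconstruction settings the calibration will serve
(a grid search under a lighter, single-sample configuration selects
different optima than the averaged reconstruction actually used, and the
fitted map then transfers poorly) — and records, as the observed optimum,
the *smallest* grid point within 0.3 dB of the PSNR maximum: for nearly
unchanged pairs the curve is flat and a raw argmax is sampling noise; the
parsimonious rule mirrors the tie-break above. The affine fit is ordinary
least squares over ≥3 pairs and refuses degenerate (zero-variance)
proxies.

AutoInit produces, from a fast prior-free reconstruction (fixed
`t_p=200, n_opt=5, n_step=80, n_avg=1`): the initial phase
`φ = ∠x_init`, the prior rigidly registered to `|x_init|` (phase
correlation over an exhaustive ±30° rotation grid; a normalized
cross-correlation below 0.2 falls back to the identity with a warning),
and the calibrated hot-start timestep from
`TimeProject(E(|x_P| e^{jφ}), E(x_init))`. For controlled-misregistration
studies the registration step can be disabled (`register=False`) so the
timestep selection must absorb the misalignment — that is the scenario in
which the selected t_p is expected to rise with severity, whereas with
registration enabled the rigid transform simply removes it.

## Posterior sampling (LDPS core, CAPS, LAPS)

Each DDIM step is followed by `n_opt` Adam updates of the current latent
on `‖y − A(D(E[z0|z_t]))‖²`, with the gradient carried through both the
Tweedie map (including the score network's input Jacobian, re-linearized
at every inner step) and the decoder. Defaults follow the reference
operating point: `n_opt=10`, `n_step=100`, `n_avg=4` averaged samples
(complex averaging, with a magnitude-mean switch), 6 CG iterations of
image-space output data consistency `min ‖Ax−y‖² + λ‖x−x_dec‖²`
(λ=1e-2 relative to data scale), Adam step size 1e-2 on latents with
optimizer state reset at each diffusion step so steps are comparable
across t. The hot-start timestep snaps to the nearest DDIM grid point and
steps above it are skipped, so hot-starting also shortens sampling. CAPS
initializes from an encoded CG-SENSE reconstruction projected to
`t_p=200`; LAPS initializes from the phase-modulated registered prior at
the AutoInit-selected `t_p`. Every sample draws its own seeded generator;
full runs are bit-reproducible.

A known approximation property, measured in the linear-Gaussian
validation: Adam's scale-free steps inject drift of order
`n_step·n_opt·lr` into directions the operator barely measures, biasing
the sample mean away from the exact posterior mean as the step size
grows. The validation therefore runs with a reduced latent step (5e-3)
and the statistically matched output-DC weight λ=σ², under which the
empirical sample mean agrees with the closed-form posterior mean within 3
Monte-Carlo standard errors and the sample covariance matches the
posterior covariance trace within a few percent.

## Classical baselines

L1-wavelet CS uses an orthonormal Daubechies-4 transform (periodized, 4
levels at ≥128 px, adapted down at small fixtures) solved by FISTA with
adaptive restart; step size 1/2 from `‖AᴴA‖ ≤ 1`. LACS adds an L1
proximity term to the registered prior,
`λ1‖W1 Ψx‖₁ + λ2‖W2(x−x_P)‖₁`, with inverse-magnitude weights
`W ← 1/(|·|+ε_w)`, `ε_w=1e-3`, normalized to unit mean and refreshed each
outer iteration (iteratively reweighted L1). The two-prox inner problem
is solved by generalized forward–backward splitting with a best-iterate
guard, so the reported objective trace is non-increasing at fixed
weights; with λ2=0 the solver reduces exactly to the reweighted CS path.
λ1=λ2=2e-3 were fixed once on synthetic fixtures.

## Synthetic longitudinal data

Phantoms are random soft-edged ellipse/blob compositions with mild smooth
texture on [0,1]; change presets apply lesions, cavities, smooth
deformations and contrast drift with expected changed-pixel fractions of
≈1% (low), ≈5% (med) and ≈15% (high), a documented stand-in for
radiologist change grades; lesions/cavities use compactly supported
cosine-tapered discs so change maps match their nominal areas.
Misregistration is rigid (quintic-spline resampling) plus a
"slice-offset" surrogate that blends in a strongly deformed copy of the
anatomy to mimic through-plane mismatch. A pair bundles the prior
magnitude, the phase-augmented follow-up, its noisy undersampled k-space,
the change map, and all seeds; with no change, no misregistration and no
noise the stored k-space equals the forward model of the follow-up
exactly.

What the generator does *not* emulate: real tissue contrast families,
anatomically plausible lesion appearance, coil-noise correlation, motion
or off-resonance artifacts, and clinical registration failure modes.
Passing orderings at this scale show the machinery behaves as designed,
not that clinical effect sizes are reproduced.

## Study conditions and problem sizes

The desk-scale study (shared by the test suite and
`scripts/acceptance.py` through `lapsmri.toy`): 64×64 phantoms, 8 coils,
σ=0.005 (≈30 dB measurement SNR), 1-D variable-density R=6 with 8 center
lines; codec trained on 200 phantoms; score network width 48 / depth 2 /
50 epochs on 400 flip-augmented latents (≈3 min on one CPU); calibration
on 6 mixed-severity pairs over the grid {50,250,…,850} with
`n_step=50, n_opt=6, n_avg=2`; reconstruction config
`n_step=50, n_opt=6, n_avg=4`. The longitudinal
ordering is measured over 20 pairs in the tests and 12 in the acceptance
script; misregistration over 4 and 3 pairs respectively. Larger settings
sharpen every margin but do not change any ordering.

## Known limitations

- The toy diffusion prior is far weaker than a fine-tuned large UNet;
  absolute PSNR values are not comparable to clinical-scale results, only
  orderings and mechanism-level properties are.
- The linear codec's bottleneck loss at 64×64 caps latent-only
  reconstruction quality; output DC compensates in measured directions.
- The hot-start theory assumes `z0 ~ N(0,I)`; phantom latents violate this
  (they are clustered), which the affine calibration absorbs at the cost
  of dataset-specific constants.
- Rigid registration only (rotation+translation); no deformable or
  through-plane correction.
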