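# Methods

## The model

MorphLDM is a two-stage generative model for 3D structural brain images
built on the template assumption: every subject volume `x` is a warped
copy of a shared template, `x = v ∘ x̄` with `v = Id + u` a dense
deformation. Modeling the image population then reduces to modeling the
population of displacement fields `u`, which concentrates capacity on
morphology rather than intensity.

**Stage 1 (deformation autoencoder).** A template decoder `x̄(·)` emits
the template — from a learnable input vector in the unconditional model,
or from the condition vector `c = (age/100, sex)` in the conditional
variant, which yields condition-specific templates. An encoder
`E_θ(x, x̄)` sees the image and template concatenated on the channel axis
and outputs a Gaussian latent grid `z` (mean and log-variance per
element, 8 channels at 1/8 spatial resolution: three stride-2 levels). A
deformation decoder `D_φ(z)` maps the latent to a full-resolution
3-channel displacement field, applied to the template by a differentiable
trilinear grid-sampler. All three networks train jointly on a
registration objective

```
L = L1(warp(x̄, u), x) + α·mean|u|² + β·mean|∇u|²
    + λ_KL · KL(z ‖ N(0,1)) + λ_adv · L_G + λ_cent · mean|ū_batch|²
```

with α = 5, β = 1, λ_KL = 1e-7, λ_adv = 0.005 (least-squares patch
discriminator), forward-difference gradients, and means taken per voxel.
In the conditional variant `c` is also appended to `z` as constant
channels across the latent grid and fed to the template decoder.

**Stage 2 (latent diffusion).** A DDPM with ε-prediction is trained on
the stage-1 latents (standardized by one scalar, 1/std over the training
set): `z_t = √ᾱ_t·z₀ + √(1−ᾱ_t)·ε`, and a time-conditioned 3D UNet
`ε_ω(z_t, t, c)` minimises `E‖ε − ε_ω‖²`. Conditioning enters through
single-head cross-attention over two learned condition tokens at the two
coarsest UNet levels. Generation draws `z_T ~ N(0,1)`, runs ancestral
DDPM (or deterministic DDIM) in reverse, decodes the latent to a
displacement field, and warps the template. In the conditional variant
the appended condition channels are rebuilt from the requested `c` at
generation time; they are never denoised.

## Design choices where the design was open

* **Numerical core.** All networks, the autograd engine, the 3D
  convolutions and the differentiable grid-sampler are implemented
  directly on numpy. At desk scale (16–32 voxel grids, 10³–10⁴ batch
  steps) this trains in minutes on one CPU and is bit-reproducible from
  a seed, which the determinism contracts rely on.
* **Displacement units.** Fields are stored in voxel units and
  `displacement_regularizer` reports R(v) in voxel units. *Inside the
  training objective* the displacement is measured in normalized grid
  coordinates (voxels × 2/extent per axis, the grid-sampler convention)
  before applying α and β. This keeps the weights genuinely
  resolution-independent; with voxel units a 1-voxel RMS field would
  cost α·1 = 5, two orders above the entire similarity term, and all
  deformation collapses.
* **Unbiased-template (centrality) penalty,** weight 100 on the squared
  batch-mean normalized displacement. Without it the fields share a large
  systematic component (the template never absorbs the common residual)
  and the template does not sit at the deformation centroid of the
  cohort; with it the cohort-mean field norm falls to ~0.3–0.4× the mean
  per-subject field norm on the desk runs. This is the standard device
  of learned unbiased atlas construction.
* **Tight posterior initialization.** The log-variance head starts at
  −6 (σ ≈ 0.05). A unit-variance start drowns the per-subject latent
  signal in sampling noise and the deformation decoder learns to ignore
  `z` entirely; the KL weight (1e-7) is far too small to matter at
  initialization. The KL penalty's role — keeping the *latent space* the
  diffusion model consumes from drifting to extreme scales — is checked
  on the cohort-level element variances of the standardized latents
  (band [0.1, 10]), not on the posterior σ².
* **Zero-initialized heads.** The deformation head and the diffusion
  UNet output head start at zero: training begins exactly at the
  identity deformation, and the untrained denoiser is exactly the zero
  predictor (loss 1 per element).
* **Noise schedule.** Linear betas 1e-4 → 2e-2 are the DDPM endpoints
  stated for T = 1000; shorter schedules rescale the betas by 1000/T so
  the terminal ᾱ_T stays ≈ 2e-5 and the forward process still ends at
  the N(0,1) prior that sampling starts from. Desk default T = 100.
* **GAN objective** is least-squares on a 3-layer strided patch critic;
  the critic compares the deformed template against the real image (the
  quantity the similarity loss also sees).
* **Latent export for diffusion** uses the reparameterised sample of
  `z` (mean-only export is available via `transform(sample=False)`).

## The phantom generator

Real cohorts of this kind are tens of thousands of MNI-registered
skull-stripped T1w volumes; the bundled generator emulates the features
of such data that the model's claims rest on, at desk scale. A phantom is
a nest of ellipsoids in a 16³–32³ grid: an outer "head" shell whose
boundary carries a radial sinusoidal folding perturbation (frequency 6,
amplitude 0.06, phase shifted by π/2 for sex = 1 — a morphological, not
intensity, sex signal), a "brain" compartment (slight age-related
shrinkage, small sex-dependent radius offset), a central "ventricle"
whose normalized radius grows by +0.10 over the 0–100-year age range
(the generosity is deliberate: age must be recoverable from volume
alone for the recovery tests to be well-powered), and two lateral
nuclei. Region intensities are distinct, so ground-truth labels are
recoverable from the noiseless image by midpoint thresholding — the
stand-in for an external segmentation tool. Gaussian smoothing
(σ = 0.5 voxel) and additive intensity noise (SD 0.02) are applied last.

What the phantoms do *not* emulate: MRI physics (bias fields, k-space
artifacts), registration error, skull-stripping failures, topological
variability of real cortex, and intensity differences between
scanners. Passing the recovery tests therefore shows the pipeline is
correct and can recover morphological condition effects it was designed
for — not that it reaches any particular fidelity on real MRI.

## Problem sizes

Desk-scale runs used throughout the tests and the acceptance script:
16³ grids, 64 training phantoms, stage 1 for 40 epochs at batch 8
(Adam, lr 2e-3, cosine decay), stage 2 for 800 steps at batch 16, toy
diffusion for 3000 steps, 50 held-out subjects, 50 generated samples
over ages 5–95. The `desk32` preset scales the same settings to 32³ and
200 subjects; `paper_full` records the full-scale constants
(160×192×176 grids, UNet channels [384, 512, 512], T = 1000), which are
not intended to run on a desktop.

## Numerical notes and degenerate inputs

* Warp out-of-bounds handling defaults to border replication (zeros
  optional); gradients through clamped samples are zeroed.
* Jacobian determinants and the regularizer's ∇u use forward differences
  with a replicated edge (the last slice contributes zero difference).
* MS-SSIM reduces its scale count for small grids (each scale halves the
  volume; the window needs ~12 voxels per side) and renormalises the
  standard 5-scale weights; grids below 12 voxels are rejected.
* Cohen's d uses the classical pooled-SD two-sample form; zero pooled SD
  with unequal means is flagged infinite, never dropped.
* The Fréchet distance symmetrises the matrix square root and clips the
  tiny negative eigenvalues that finite samples produce.
* The condition predictors regress age/100 (MSE) and classify sex
  (logistic loss) with a 3-level conv tower and global average pooling;
  their pooled penultimate features are the bundled Fréchet embedding.
* Balanced age sampling draws a nonempty decade bin uniformly, then a
  member uniformly within it (with replacement), so skewed cohorts see
  equal expected draws per decade.
* Stage-1 training aborts on a non-finite loss and restores the last
  finite epoch's weights.

## Known limitations

* No diffeomorphism guarantee: the displacement parameterisation is
  unconstrained (no velocity-field integration); `jacobian_determinant`
  reports the nonpositive-determinant fraction as a diagnostic instead.
* The desk-scale networks are far below the full-scale widths; the
  conditional variant carries most of the age signal through the
  condition-dependent template, with the diffusion latents adding
  subject variability around it.
* Generated volumes are visibly smoother than phantoms (small decoders,
  L1 similarity), so threshold segmentation of generated images is less
  exact than on ground-truth labels; regional-volume effect sizes of
  generated cohorts are correspondingly conservative, and for the small
  regions (nuclei, thin head shell) they are dominated by segmentation
  threshold effects rather than by generator quality. Note also that
  Cohen's d is a pairing-insensitive marginal statistic: permuting the
  condition assignment of a generated cohort does not change its d
  values, so effect-size comparisons only discriminate generators whose
  regional-volume *marginals* differ.
* The evaluation predictors share the training distribution with the
  generator's training cohort; on real data one would hold out an
  independent validation split for them.
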