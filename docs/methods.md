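# Methods

`usdenoise` implements a residual-learning UNet variant for removing
speckle-like noise from 2-D grayscale ultrasound-style images, together
with the classical and learned baselines it is usually compared against,
the PSNR/SSIM evaluation machinery, a synthetic phantom generator that
makes the whole pipeline runnable without any clinical data, and a small
module for clinical outcome arithmetic from printed group summaries.

## Noise model and sign convention

All noise handling follows the decomposition

    a + e = b,

where `a` is the noisy image, `b` the clean image and `e` the correction
that restores it (`e = b - a`).  This is deliberately the reverse of the
more common "noisy = clean + noise" convention: the learned denoiser
predicts `e` directly, so the clean estimate is `b_hat = a + e_hat`.

Two noise generators are provided:

* **multiplicative speckle** (default): `a = b + b*eta`,
  `eta ~ N(0, (sigma * 0.2)^2)` i.i.d.  Fully developed speckle in real
  B-mode imaging is Rayleigh-type and spatially correlated by the point
  spread function; the multiplicative Gaussian used here reproduces the
  signal-dependent variance that distinguishes speckle from additive
  noise but none of the spatial correlation.
* **additive Gaussian**: `a = b + g`, `g ~ N(0, sigma_px^2)` i.i.d.

The benchmark noise axis uses dimensionless levels sigma in
{0.5, 1, 1.5, 2, 2.5}.  For the additive model these map to pixel units
as `sigma_px = 25.5 * sigma` (so the five levels span 12.75–63.75 grey
levels on an 8-bit image, visually light to heavy); for speckle, sigma
scales a relative fluctuation of `0.2 * sigma`.  Both factors are
config constants, chosen once so that sigma = 1 corresponds to clearly
visible but recoverable corruption (noisy-input PSNR near 19–20 dB) and
sigma = 2.5 to severe corruption.

Noisy images are clipped to the valid 8-bit range; `e` is then
*recomputed* as `b - a`, so the identity `a + e = b` holds exactly
(within one float64 ulp) for every emitted sample, including clipped
pixels.  This is asserted by the `NoisySample` constructor itself.

## Phantom generator

Each phantom emulates the appearance of an ovarian-cyst B-mode scan: a
hypoechoic (dark) elliptical cyst over brighter tissue-echo texture,
with a configurable number of small bright floaters inside the cyst.
Texture is Gaussian-blurred white noise renormalised to a target
standard deviation (default 20 grey levels, correlation length 1.5 px)
and clipped at ±3 sd so that "the cyst interior is dark" is an exact
construction property, not a probabilistic one.  Default geometry:
64×64 image, cyst semi-axes 18×14 px, cyst mean 40, background mean
160.  Corpus generation jitters geometry, contrast and floater count
per image from per-sample seeds spawned off one master seed.

What the phantoms do **not** model: acoustic shadowing/enhancement,
point-spread-function anisotropy, depth-dependent gain, scan-conversion
geometry, real anatomical variability.  Passing results on this corpus
therefore demonstrate that the implementation learns and measures what
it claims on signal-dependent noise with known ground truth — not
clinical-grade performance on real ultrasound.

## Metrics

* **MSE**: mean squared pixel difference.
* **PSNR** = `10 log10((2^n - 1)^2 / MSE)` dB with n = 8 by default;
  identical images return an explicit `inf` sentinel rather than
  raising, and benchmark tables render it as `inf`.
* **SSIM** uses the single-statistic form
  `(2 u_X u_Y + C1)(2 cov + C2) / ((u_X^2 + u_Y^2 + C1)(var_X + var_Y + C2))`
  with population (divide-by-N) variances and the field-standard
  constants `C1 = (0.01 L)^2`, `C2 = (0.03 L)^2`, `L = 2^n - 1`
  (overridable).  The default **global** mode evaluates the formula
  once over the whole image, matching the formula as written; a
  **windowed** mode (8×8 non-overlapping tiles, averaged) is provided
  since published SSIM numbers are usually windowed.

## The improved UNet

Architecture (`ArchitectureSpec.improved_unet`):

* encoder of `depth` levels; at each level a residual block (two 3×3
  convolutions with a per-channel PReLU between, identity skip) followed
  by a stride-2 3×3 convolution that halves H×W and doubles channels —
  downsampling by strided convolution instead of max pooling;
* decoder mirror: nearest-neighbour 2× upsampling + 3×3 convolution,
  concatenating same-level skip connection, a fusing 3×3 convolution and
  a residual block;
* a feature-recovery branch per level (RDUB): the encoder feature map is
  passed through a residual block and a channel-matching 1×1
  convolution and **added** element-wise onto the decoder map, on top of
  the concatenating skip.  The textual description this realises is
  one sentence long; this is the shape-consistent reading of
  "copy, splice and superimpose";
* a reconstruction head (Recon): 3×3 conv (C → C/2), PReLU, 3×3 conv
  (→ 1 channel), linear output — the predicted noise map `e_hat`.

PReLU is `x` for `x > 0` and `t_f * x` otherwise, with one learnable
slope per channel (a shared-slope mode exists); slope 0 degenerates to
ReLU.  Slopes start at 0.25; convolutions use He fan-in initialisation
from a fixed seed with biases at zero, except that the *last*
convolution of every additive branch — the second conv of each residual
block, the RDUB 1x1, and the final Recon conv — is zero-initialised
(fixup-style).  A freshly built residual-learning model is therefore
the exact identity denoiser, which makes training stable for every
seed; with He initialisation throughout, the stacked additive branches
blow the forward pass up for some seeds.  Model construction is
bit-reproducible from the init seed.

Inputs are scaled to [0, 1] inside the network; the residual is
predicted on that scale and undone on output, with the clean estimate
formed on the original pixel scale (`b_hat = a + 255 * net(a/255)`), so
a zeroed reconstruction head makes `denoise` the bitwise identity.
Inputs whose sides are not multiples of `2^depth` are reflect-padded and
cropped back (strict mode raises instead).

Defaults are depth 2, base 8 channels (≈ 54k parameters).  The source
description of this architecture is schematic — no layer counts,
widths or depth are stated anywhere — so these defaults are explicit
configuration sized for single-CPU training, not a fidelity claim.

## Baselines

* **Plain UNet**: classic codec — double 3×3 conv + ReLU blocks, 2×2 max
  pooling (channel doubling in the convolution after the pool),
  concatenating skips, single-conv head, and *direct* prediction of the
  clean image (no residual learning).
* **Flat CNN**: 5 layers × 16 channels of 3×3 conv + ReLU, no
  down/upsampling, no skips, direct prediction.  The comparator this
  stands for is never described beyond its name; depth/width are
  documented arbitrary choices.
* **NL-means**: weights `exp(-||P_i - P_j||^2 / h^2)` over a clipped
  search window (patch SSD is a plain sum over reflect-padded square
  patches), normalised to sum to 1 per pixel.  Implemented in-repo in a
  vectorised offset formulation and tested to 1e-9 against a literal
  double-loop oracle; the library routine in scikit-image uses a
  noise-compensated weight kernel and would not match that definition.
  The strength helper sets `h^2 = 2 sigma^2 p^2`, twice the expected
  patch SSD between two noisy realisations of the same patch, which is
  the smallest `h` that does not treat pure-noise differences as
  structure.  Defaults: patch 5, window 13.

## Training

Mini-batch Adam (default lr 1e-3, batch 16) on plain MSE: against the
residual `e` for the improved UNet, against the clean image for the
direct-prediction baselines (a mismatched loss/model pairing is a
config error).  MSE is the canonical choice when model quality is
scored by PSNR, which is a monotone transform of MSE.  Training uses one
random 32×32 crop per image per epoch — crops cost a quarter of
full-image batches and denoising statistics are translation-local, so
this buys a ~4× speedup at equal epoch count on a single CPU —
while validation and inference always run on full images.  Data order,
crop positions and initialisation all derive from the configured seed;
two runs with the same config are bit-identical.  No early stopping
(fixed epochs keeps runs deterministic).  A final quality gate
(validation PSNR ≥ noisy-input PSNR) is logged as a warning, never an
error.

## The pinned desk-scale experiment

One reproducible end-to-end run sized for a single CPU
(`usdenoise.experiments`): 200 speckle phantoms (64×64) at sigma = 1.0,
80/20 split, 30 epochs per learned model, then PSNR/SSIM grids over
{identity, NL-means, flat CNN, plain UNet, improved UNet} ×
{0.5, 1, 1.5, 2, 2.5} on a freshly seeded 50-image corpus.  The whole
run takes roughly 5–8 minutes.  Learned models are trained once at
sigma = 1.0 and shared across the sigma columns (per-sigma training is
supported by passing `(name, sigma)`-keyed checkpoints).

At this scale every method clears the identity floor at sigma = 1.0 by
a wide margin (the improved UNet by ~9 dB of validation PSNR), and the
identity-start initialisation lets the improved UNet lead the learned
baselines by ~2.5 dB of benchmark PSNR.  The ranking among the learned
methods is nevertheless training-dependent at desk scale, so the
benchmark hard-asserts only the floor comparisons and monotonicity and
reports the improved-vs-plain comparison with a paired bootstrap
interval instead of asserting it.

## Clinical outcome arithmetic

`usdenoise.clinical` ingests printed per-group summaries (a YAML
fixture transcribing the two 50-patient nursing groups ships with the
package): per-complication patient counts, satisfaction category
percentages, and (mean, sd) pairs.  Complication rate is
`100 * sum(counts) / n` under a documented one-complication-per-patient
assumption (enforced: counts summing beyond n raise).  Total
satisfaction is `(very satisfied + satisfied) / n`, accepted as counts
or percentages — percentages are canonical because the printed values
imply non-integer counts at n = 50.  Group comparisons use the
two-sample t-test from summary statistics (pooled by default, Welch
available; the source does not say which was used).  The printed
statistic/p-value columns of the source's baseline table are internally
inconsistent (e.g. t = 1.578 paired with p = 0.674 at n = 100) and are
deliberately not ingested or reproduced; only means and sds are.  The
fixture also flags a units discrepancy for operation time between the
source's abstract (days, sd 6.13) and results section (minutes,
sd 16.13); the results-section values are transcribed.

## Numerical choices

* The autodiff engine stores arrays as float32 (configurable; tests
  switch to float64 for finite-difference gradient checks, which pass to
  1e-7 absolute).  Convolution is im2col + matmul with the column matrix
  cached for the backward pass.
* PSNR of identical images: `inf` sentinel, never an exception.
* PReLU uses the `x <= 0` branch at exactly zero (both branches give 0).
* Max-pool backward routes gradient to the first argmax on ties.
* Checkpoints are single `.npz` files with a JSON header (architecture,
  kind, trained flag) plus parameter arrays in construction order.

## Known limitations

* Phantoms lack spatially correlated speckle and scan geometry; results
  do not transfer to clinical images without retraining and re-tuning.
* The published PSNR/SSIM comparison table this harness mirrors in
  *structure* was computed on an unavailable clinical dataset with
  unstated noise units and training regimen; its numeric values are out
  of scope and not comparable to numbers produced here.
* Single-channel 2-D only; no GPU path; desk-scale training sizes.
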