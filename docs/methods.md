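# Methods

## Overview

`omicsdiff` implements a conditional denoising diffusion model for
radiogenomic image synthesis: 2D grayscale medical-image projections are
generated from Gaussian noise, steered by a per-patient condition vector
derived from multi-omic data (gene expression, DNA methylation, copy-number
variation).  The package covers the full workflow — image and omics
preprocessing, the diffusion core, the conditioned U-Net denoiser, the
evaluation metrics, and a synthetic paired-data generator that makes every
stage testable at desk scale on one CPU.

## The diffusion model

The forward process is the standard Gaussian Markov chain

    q(x_t | x_{t-1}) = N(x_t; sqrt(1 - beta_t) x_{t-1}, beta_t I),

with a variance schedule 0 < beta_1 <= ... <= beta_T < 1.  With
alpha_t = 1 - beta_t and alpha-bar_t the running product, the closed form

    x_t = sqrt(abar_t) x_0 + sqrt(1 - abar_t) eps,  eps ~ N(0, I)

lets training jump straight to any timestep.  The true reverse conditional
q(x_{t-1} | x_t, x_0) is Gaussian with variance
beta-tilde_t = (1 - abar_{t-1})/(1 - abar_t) beta_t and a mean expressible
either in (x_t, x_0) or, after substituting the noise parameterisation, in
(x_t, eps); the package implements both forms and tests their agreement.
A U-Net eps_theta(NI, t, tau) is trained on the simplified objective
||eps - eps_theta||^2 with t ~ Uniform{1..T}, and generation runs the
ancestral sampler

    x_{t-1} = (x_t - (1-alpha_t)/sqrt(1-abar_t) eps_theta) / sqrt(alpha_t)
              + sigma_t z,

with z = 0 at t = 1 and the final sample clipped to the training range
[-1, 1].

Schedule parameters are nowhere pinned down by the modelling problem itself,
so they are configuration: linear schedule, T = 1000, beta in
[1e-4, 0.02] for full-scale runs; T = 50 everywhere in the test suite.  The
boundary convention abar_0 := 1 makes all formulas total at t = 1 (and gives
beta-tilde_1 = 0).  Sampler noise defaults to sigma_t^2 = beta_t, with
sigma_t^2 = beta-tilde_t as an option; the two coincide as T grows and the
choice is empirically immaterial at desk scale.

## Conditioning

The condition vector tau (R latent factor scores, z-scored per factor) acts
through three pathways:

1. **Inner-product fusion** at the input: tau is linearly extended to an
   n x n map F (a learnable dense R -> n^2 map, small random init, zero
   bias), the matrix product X = F P with the noisy image P is formed, and
   the denoiser receives NI = P + gate * X.  The scalar gate starts at 0 so
   early training matches the unconditional model — the raw product F P can
   otherwise dwarf P.
2. **Cross-attention** at the U-Net bottleneck: tau is lifted to a small
   set of condition tokens (default 4); queries come from the condition
   tokens, keys/values from the flattened bottleneck positions,
   A = softmax(Q_A K_B^T / sqrt(d_k)) row-wise (max-stabilised), and the
   fused representation FR = (A V_B) W_OB is token-averaged into a
   per-channel bias added through a second zero-initialised gate.
3. **Time-embedding injection**: a linear map of tau is added to the
   sinusoidal timestep embedding, which every conv block receives as an
   additive per-channel bias.

Pathway 3 is on by default, and deliberately so.  In controlled runs on the
synthetic cohort (128 pairs, 16 x 16, T = 50, 150 epochs) pathways 1 + 2
alone reduced the loss as well as the full model but produced a
directionally correct blob shift for a +-2 positional condition in only
23/40 paired samples — chance level.  Adding pathway 3 gives 40/40 with the
same loss.  The reason is structural: both the gated fusion and the
attention bias modulate the image through the image content itself, and at
the start of sampling that content is pure noise, so the condition signal
they carry is second-order.  The time-embedding route injects tau directly
at every stage regardless of image content, the same mechanism by which
class-conditional diffusion models inject class embeddings.  All three
pathways are independently switchable for ablation.

## The denoiser

A small shape-preserving U-Net: per-stage blocks of 3x3 convolution, group
normalisation (4 groups), additive time-embedding bias and SiLU gating; 2x
average-pool downsampling; nearest-neighbour upsampling with skip
concatenation; bottleneck cross-attention as above.  Defaults are depth 3,
base 32 channels, multipliers (1, 2, 4), two blocks per stage — sized so a
16 x 16 model (depth 2, base 16, ~93k parameters) trains on one CPU in
minutes.  The final conv is scaled down (x0.1) at init so the untrained
model predicts small noise and early sampling stays numerically tame, while
still letting gradient reach every upstream parameter group.

The entire network runs on a minimal tape-based reverse-mode automatic
differentiation engine over NumPy float64 arrays (`omicsdiff.nn`), written
for this package: broadcasting arithmetic, matmul, im2col convolution,
pooling/upsampling, group norm composed from primitives, stabilised softmax,
and Adam.  Every primitive's gradient is verified against central finite
differences in the test suite; float64 keeps those checks at 1e-4 relative
tolerance without noise from accumulation error.

## Preprocessing

**Images.**  3D volumes (NIfTI) are collapsed to 2D orthographic
projections — maximum-intensity projection along the sagittal axis by
default, the standard 2D rendering for contrast-enhanced breast MRI (mean
projection available).  Projections are resized with the nearest-pixel rule
`src_index = floor((i + 0.5) * src/dst)` (half-pixel centers, tie-free,
no new intensity values) to a square target, 128 x 128 at full scale, and
min-max normalised: [-1, 1] for diffusion training, [0, 1] for storage and
metrics (SSIM's constants assume a declared dynamic range).  Constant images
map to the range midpoint.

**Omics.**  Per-modality patient x gene matrices are cleaned by removing
all-zero rows/columns (iterated to a fixed point), then genes are ranked by
coefficient of variation CV = std/|mean| (sample std; a zero-mean gene
counts as maximally variable; ties break lexicographically) and the top
fraction (default 10%) is kept.  CV is computed on the expression modality
by default — methylation beta-values and copy-number ratios have scales
that make CV ill-behaved — and is configurable.  The aligned matrices are
stacked into a patients x genes x modalities tensor (all axes sorted, so
the result is invariant to input ordering) and factorized at rank R
(default 17) by alternating-least-squares CP decomposition with seeded
random initialisation.  ALS solves the three linear subproblems exactly per
sweep, so the recorded reconstruction-error trace is monotone
non-increasing; iteration stops when the relative error improves by less
than 1e-8, and non-convergence within `max_iters` sets a diagnostics flag
rather than raising.  A Bayesian treatment of the factorization
(posterior uncertainty on the factors) is out of scope; only the point
estimate feeds the conditioning.

## Evaluation metrics

FID is computed between Gaussian fits (mean, N-1 covariance) of image
embeddings, with the matrix square root obtained from the symmetric
stabilisation sqrt(S1) S2 sqrt(S1) via eigendecomposition, clipping
eigenvalues below 0 at tolerance 1e-8 — identical sets score exactly 0 and
equal-covariance mean shifts score ||d||^2.  The default embedding backend
is raw pixels (optionally PCA-reduced); an inception-style CNN backend
requires externally supplied pretrained weights and is intentionally not
bundled, so absolute FID values here are not comparable to CNN-embedding
FIDs reported elsewhere — the metric identities hold for any backend.
FID-STD is defined as the sample standard deviation of per-batch FIDs of
equal-size generated batches against the whole real set.  SSIM follows the
luminance/contrast/structure form with c1 = (k1 L)^2, c2 = (k2 L)^2
(k1 = 0.01, k2 = 0.03), in both a global-moments mode and a 7 x 7
sliding-window mode (sample moments; verified against scikit-image).

## Synthetic paired cohort

The fixture generator emulates exactly the statistical structure the model
assumes: patient factor scores drawn i.i.d. N(0, 1); a grayscale phantom
image per patient (Gaussian-profile ellipse on a dark background) whose
center x/y, radius and peak intensity are monotone functions of four
designated factors, plus Gaussian pixel noise (sd 0.02); and three omics
matrices scores @ (B * c_m)^T + noise sharing a planted rank-R trilinear
signal, where B is a shared gene-loading matrix and c_m per-modality signed
weights (magnitude 0.5-1.5; the sign diversity mirrors, e.g., methylation
anti-correlating with expression, and keeps the CP factors identifiable).
A +-2 SD swing of a positional factor moves the blob center by ~36% of the
image width — detectable by a tiny model, safely inside the frame.  A
decoder measures centroid, area-equivalent radius (rescaled by the
half-peak width of the radial profile so generator and decoder agree) and
peak, making conditioning effects quantifiable without inspection.

What the fixtures do *not* emulate: anatomy, scanner physics, intensity
inhomogeneity, the heavy-tailed and batch-structured noise of real omics,
and realistic sample sizes.  Passing tests therefore demonstrate that the
machinery is correct and that the conditional signal path works end to end;
they say nothing about image realism on clinical data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at reduced
scale, chosen as the smallest sizes at which every mechanism is exercised
and stochastic checks are stable: 128 patients, 16 x 16 images, rank-8
factors, T = 50, a depth-2/base-16 U-Net (~93k parameters), 150 training
epochs at batch 16 (Adam, lr 2e-3), 40 paired samples per directional
comparison.  Directional comparisons use common random numbers (the same
sampler seed for both condition signs) so each pair differs only through
the condition.  One root seed fans out to per-purpose generators (init,
timestep draws, training noise, sampler noise, shuffling) via SeedSequence
spawning; identical seeds give bit-identical runs.

Degenerate inputs are handled explicitly: constant images normalise to the
range midpoint; an all-zero image decodes to a null record; a zero-mean
gene gets infinite CV; beta-tilde_1 = 0 by the boundary convention;
cross-attention logits are max-subtracted before exponentiation; FID clips
tiny negative eigenvalues; k = 1 cross-validation (no training complement)
and k > N are rejected.

## Known limitations

- The pixel/PCA embedding backend makes FID magnitudes dataset-specific;
  only identities and relative comparisons are meaningful.
- CP-ALS finds a local optimum; near-collinear factors can slow it to a
  swamp.  Seeded initialisation keeps results reproducible, and the
  diagnostics expose the error trace.
- The training loop is plain NumPy on one CPU; it is sized for method
  validation, not for 128 x 128 clinical-scale training.
- Whether the source imaging pipeline used max- or mean-intensity
  projection, and its normalisation, is not recoverable; both are explicit
  configuration, not guesses.
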