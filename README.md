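# omicsdiff

Conditional denoising diffusion for radiogenomic image synthesis: generate
2D grayscale medical-image projections from per-patient **multi-omic
latent factors**.

## The problem

Radiogenomics links imaging phenotypes to genomic profiles, but paired
image + omics cohorts are rare — typically a handful of patients have both
while hundreds have omics only.  A generative model trained on the paired
subset can synthesize images for the omics-only patients, enabling
image-based downstream analyses where no images exist.  `omicsdiff` is for
researchers who want that machinery with every component testable offline:
the preprocessing (volume projection, omics tensor factorization), the
conditional diffusion model itself, the evaluation metrics (FID, FID-STD,
MSE, SSIM), and a synthetic paired-data generator for validation.

## The model

A denoising diffusion probabilistic model with a multi-omic condition.
The forward chain corrupts an image x₀ with scheduled Gaussian noise,
q(x_t | x_{t−1}) = N(√(1−β_t) x_{t−1}, β_t I), giving the closed form
x_t = √ᾱ_t x₀ + √(1−ᾱ_t) ε with ᾱ_t = ∏(1−β_i).  A U-Net ε_θ(NI, t, τ)
learns to predict the noise, minimising ‖ε − ε_θ‖², and sampling runs the
ancestral reverse chain

    x_{t−1} = (x_t − (1−α_t)/√(1−ᾱ_t) · ε_θ(x_t, t, τ)) / √α_t + σ_t z.

The condition τ is a rank-R factor-score vector (default R = 17) from an
alternating-least-squares CP decomposition of a patients × genes ×
modalities tensor built from CV-filtered expression, methylation and
copy-number matrices.  τ steers generation through a gated inner-product
fusion at the input (NI = P + gate·F(τ)·P), cross-attention at the U-Net
bottleneck (A = softmax(Q_A K_Bᵀ/√d_k)), and a per-stage time-embedding
injection.  The whole training stack runs on a built-in NumPy autodiff
engine — no deep-learning framework required.

## Worked example

Train a small conditional model on the synthetic paired cohort (phantom
images whose blob position/size/intensity are controlled by known latent
factors) and verify that the condition steers generation:

```python
import numpy as np
from omicsdiff import (ConditionalDiffusionModel, DenoiserConfig,
                       FixtureSpec, make_schedule)
from omicsdiff.synthetic import decode_image

spec = FixtureSpec(n_patients=128, image_size=16, rank=8, seed=7)
cfg = DenoiserConfig(image_size=16, cond_dim=8, base_channels=16, depth=2,
                     channel_mults=(1, 2), time_embed_dim=32)
model = ConditionalDiffusionModel.from_fixture(
    spec, schedule=make_schedule("linear", T=50), config=cfg)
res = model.fit(epochs=150, batch_size=16, lr=2e-3, seed=1)
print(res.summary())

tau = np.zeros(8); tau[0] = 2.0       # held-out condition: blob far right
right = res.sample(np.tile(tau, (40, 1)), seed=5)
left  = res.sample(np.tile(-tau, (40, 1)), seed=5)
cx_r = [decode_image(im)["cx"] for im in right]
cx_l = [decode_image(im)["cx"] for im in left]
print(f"mean centroid x: +2 -> {np.mean(cx_r):.2f}, -2 -> {np.mean(cx_l):.2f}")
print(f"correct direction: {sum(r > l for r, l in zip(cx_r, cx_l))}/40")
```

Output from this exact run:

```
Conditional Diffusion Model Results
==============================================
images                         128 x 16x16
condition dim (R)                8
timesteps T                     50
beta range                    1.00e-04 .. 2.00e-02
sigma mode                        beta
parameters                   93203
epochs                         150
first-epoch loss                1.0098
final-epoch loss                0.0818
loss reduction                   91.9%
root seed                        1
==============================================
mean centroid x: +2 -> 8.44, -2 -> 7.56
correct direction: 40/40
```

The loss falls by ~92% and all 40 generated pairs move the blob centroid in
the direction the condition dictates — the omics-to-image signal path works
end to end.  (The centroid separation is smaller than the generating truth;
a ~93k-parameter model trained for minutes underestimates effect sizes.)

The same workflow is scriptable from the shell:

```bash
omicsdiff make-fixtures --n 128 --size 16 --rank 8 --seed 7 --out data/
omicsdiff train --config run.yaml --data data/ --out runs/demo
omicsdiff generate --config run.yaml --checkpoint runs/demo/fold0_checkpoint.npz \
    --factors data/factors.tsv --out runs/demo/gen
omicsdiff evaluate --real data/images.npy --gen runs/demo/gen/images.npy \
    --report report.json
```

plus `prepare-images` (NIfTI → projected/resized/normalised PNG + float)
and `prepare-omics` (TSV matrices → CV filter → tensor → factor-score TSV)
for real data.

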