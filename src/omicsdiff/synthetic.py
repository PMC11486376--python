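"""Paired (image, omics) fixture generator.

Emulates the statistical structure the conditional model assumes: each
synthetic patient has an R-vector of latent factor scores drawn i.i.d.
standard normal; designated factors deterministically control the content of
a grayscale phantom image (ellipse centre x/y, radius and peak intensity,
with additive Gaussian pixel noise), and the same scores generate three
low-rank omics matrices (scores x modality-specific gene loadings + noise).
A decoder recovers the image attributes, so conditioning effects can be
measured without human inspection.

Effect sizes are chosen so a +-2 SD swing of a positional factor moves the
blob centre by ~30% of the image width — large enough for a tiny denoiser to
pick up, small enough to keep the blob inside the frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .omics_prep import MODALITIES, OmicsMatrix
from .image_prep import Projection2D

__all__ = ["FixtureSpec", "make_factors", "make_image", "make_omics",
           "decode_image", "make_paired_dataset"]


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the synthetic cohort."""

    n_patients: int = 128
    image_size: int = 16
    rank: int = 8                  # R latent factors (>= 4 controlled attrs)
    pixel_noise_sd: float = 0.02
    omics_noise_sd: float = 0.1
    n_genes: int = 60
    seed: int = 0
    # which factor controls which image attribute
    effect_map: dict = field(default_factory=lambda: {
        "x": 0, "y": 1, "radius": 2, "intensity": 3
    })
    # centre shift per factor SD, as a fraction of image width; +-2 SD then
    # spans ~36% of the width, comfortably above the 30% detectability floor
    position_scale: float = 0.09

    def __post_init__(self):
        if self.rank < len(self.effect_map):
            raise ValueError("rank must cover all controlled image attributes")
        if self.n_patients < 1 or self.image_size < 4:
            raise ValueError("degenerate fixture spec")


def make_factors(spec: FixtureSpec) -> pd.DataFrame:
    """Patient factor scores, i.i.d. standard normal, deterministic per seed."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    scores = rng.standard_normal((spec.n_patients, spec.rank))
    return pd.DataFrame(
        scores,
        index=[f"P{i:04d}" for i in range(spec.n_patients)],
        columns=[f"factor_{j + 1}" for j in range(spec.rank)],
    )


def _attributes(tau: np.ndarray, spec: FixtureSpec) -> dict:
    n = spec.image_size
    em = spec.effect_map
    cx = n / 2.0 + spec.position_scale * n * tau[em["x"]]
    cy = n / 2.0 + spec.position_scale * n * tau[em["y"]]
    radius = n * (0.22 + 0.04 * np.tanh(tau[em["radius"]]))
    peak = 0.75 + 0.2 * np.tanh(tau[em["intensity"]])
    return {"cx": cx, "cy": cy, "radius": radius, "peak": peak}


def make_image(tau, spec: FixtureSpec, rng: np.random.Generator | None = None) -> Projection2D:
    """Deterministic phantom for condition tau: dark background with a bright
    Gaussian-profile ellipse, plus (seeded) Gaussian pixel noise.

    Pixel values live in [0, 1]; the blob centre moves monotonically with the
    designated positional factors.
    """
    tau = np.asarray(tau, float)
    att = _attributes(tau, spec)
    n = spec.image_size
    yy, xx = np.mgrid[0:n, 0:n] + 0.5
    d2 = ((xx - att["cx"]) ** 2 + (yy - att["cy"]) ** 2) / att["radius"] ** 2
    img = att["peak"] * np.exp(-2.0 * d2)
    if spec.pixel_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
        img = img + rng.normal(0.0, spec.pixel_noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return Projection2D(img, value_range=(0.0, 1.0), provenance="synthetic-phantom")


def make_omics(factors: pd.DataFrame, spec: FixtureSpec) -> list[OmicsMatrix]:
    """Three modality matrices sharing the planted rank-R patient scores.

    Modality m gets values = scores @ (B * c_m)^T + Gaussian noise, where B
    is a shared gene-loading matrix and c_m a per-modality factor weight
    vector — so each modality has its own effective gene loadings while the
    stacked tensor carries an exact rank-R trilinear signal that CP
    factorization can recover.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    scores = factors.to_numpy(float)
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    gene_loadings = rng.standard_normal((spec.n_genes, spec.rank))
    # signed per-modality weights: magnitudes in [0.5, 1.5], random sign
    # (e.g. promoter methylation tracks expression with opposite sign);
    # the sign diversity also keeps the planted CP factors identifiable
    modality_weights = rng.uniform(0.5, 1.5, (len(MODALITIES), spec.rank))
    modality_weights *= rng.choice([-1.0, 1.0], modality_weights.shape)
    out = []
    for mi, mod in enumerate(MODALITIES):
        vals = scores @ (gene_loadings * modality_weights[mi]).T
        if spec.omics_noise_sd > 0:
            vals = vals + rng.normal(0.0, spec.omics_noise_sd, vals.shape)
        out.append(OmicsMatrix(
            pd.DataFrame(vals, index=list(factors.index), columns=genes), mod
        ))
    return out


def decode_image(img) -> dict:
    """Measure phantom attributes: intensity-weighted centroid, thresholded
    area-equivalent radius, and peak intensity.

    The half-peak support of the generator's radial profile exp(-2 d^2/r^2)
    has radius r * sqrt(ln2 / 2), so the area-equivalent radius is rescaled
    by that constant to put it on the generator's scale.  An all-zero image
    returns the defined null record (NaN centroid/radius, peak 0);
    translating an image translates the decoded centroid equally.
    """
    p = img.pixels if isinstance(img, Projection2D) else np.asarray(img, float)
    total = p.sum()
    if total <= 0:
        return {"cx": np.nan, "cy": np.nan, "radius": np.nan, "peak": 0.0}
    yy, xx = np.mgrid[0 : p.shape[0], 0 : p.shape[1]] + 0.5
    cx = float((p * xx).sum() / total)
    cy = float((p * yy).sum() / total)
    peak = float(p.max())
    area = float((p > peak / 2.0).sum())
    half_width = np.sqrt(np.log(2.0) / 2.0)
    return {
        "cx": cx,
        "cy": cy,
        "radius": float(np.sqrt(area / np.pi) / half_width),
        "peak": peak,
    }


def make_paired_dataset(spec: FixtureSpec):
    """Full paired cohort: (factors DataFrame, image stack (N, n, n) in
    [0, 1], list of omics matrices).  Deterministic given spec.seed."""
    factors = make_factors(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    images = np.stack([
        make_image(row, spec, rng=rng).pixels
        for row in factors.to_numpy(float)
    ])
    omics = make_omics(factors, spec)
    return factors, images, omics
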