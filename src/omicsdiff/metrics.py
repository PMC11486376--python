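"""Evaluation metrics for generated-vs-real image sets.

FID is the Frechet distance between Gaussian fits to image embeddings,
``||mu1 - mu2||^2 + Tr(S1 + S2 - 2 (S1 S2)^{1/2})``; the matrix square root
is computed through the symmetric stabilisation sqrt(S1)·S2·sqrt(S1) with
eigenvalues clipped at 0 (tolerance 1e-8), so tiny negative numerical
eigenvalues cannot produce complex distances.  The embedding backend is
pluggable: raw pixels (default, download-free), a PCA reduction of pixels,
or an inception-style CNN supplied externally.  FID-STD is the sample
standard deviation of per-batch FIDs of generated batches against the fixed
real set.  MSE and SSIM compare aligned image pairs; SSIM supports both a
global (whole-image moments) and a sliding-window mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmbeddingSet",
    "MetricsReport",
    "embed_images",
    "fid",
    "fid_std",
    "mse",
    "ssim",
]


@dataclass(frozen=True)
class EmbeddingSet:
    """N x D image embeddings with the Gaussian sufficient statistics."""

    features: np.ndarray
    extractor_id: str

    def __post_init__(self):
        f = np.asarray(self.features, float)
        if f.ndim != 2 or f.shape[0] < 2:
            raise ValueError("need an N x D feature matrix with N >= 2")
        object.__setattr__(self, "features", f)

    @property
    def mu(self) -> np.ndarray:
        return self.features.mean(axis=0)

    @property
    def sigma(self) -> np.ndarray:
        return np.cov(self.features, rowvar=False, ddof=1).reshape(
            self.features.shape[1], self.features.shape[1]
        )


@dataclass
class MetricsReport:
    fid: float
    fid_std: float | None
    mse: float
    ssim: float
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fid": self.fid,
            "fid_std": self.fid_std,
            "mse": self.mse,
            "ssim": self.ssim,
            **self.meta,
        }


def embed_images(images, extractor: str = "pixels",
                 n_components: int | None = None) -> EmbeddingSet:
    """Embed a stack of same-shape images (N, H, W) into feature vectors.

    ``pixels``: flattened intensities.  ``pca``: flattened intensities
    projected onto the top principal components (default min(N-1, 8)).
    ``inception`` requires externally supplied CNN weights and is not
    bundled; metric identities hold for any backend.
    """
    imgs = np.asarray(images, float)
    if imgs.ndim != 3:
        raise ValueError("expected a stack of 2D images (N, H, W)")
    if imgs.shape[0] < 2:
        raise ValueError("need at least 2 images")
    flat = imgs.reshape(imgs.shape[0], -1)
    if extractor == "pixels":
        return EmbeddingSet(flat, "pixels")
    if extractor == "pca":
        k = n_components or min(imgs.shape[0] - 1, 8)
        centered = flat - flat.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        return EmbeddingSet(centered @ vt[:k].T, f"pca{k}")
    if extractor == "inception":
        raise NotImplementedError(
            "the inception backend needs externally supplied pretrained "
            "weights; use extractor='pixels' or 'pca'"
        )
    raise ValueError(f"unknown extractor {extractor!r}")


def _sqrtm_psd(m: np.ndarray, clip_tol: float = 1e-8) -> np.ndarray:
    """Square root of a symmetric PSD matrix via eigendecomposition; small
    negative eigenvalues (|lambda| <= tol * max) are clipped to 0."""
    sym = (m + m.T) / 2.0
    w, v = np.linalg.eigh(sym)
    w = np.clip(w, 0.0, None)
    return (v * np.sqrt(w)) @ v.T


def fid(e1: EmbeddingSet, e2: EmbeddingSet) -> float:
    """Frechet distance between the Gaussian fits of two embedding sets."""
    if e1.extractor_id != e2.extractor_id:
        raise ValueError(
            f"embeddings from different extractors: "
            f"{e1.extractor_id!r} vs {e2.extractor_id!r}"
        )
    mu1, mu2 = e1.mu, e2.mu
    s1, s2 = e1.sigma, e2.sigma
    diff = mu1 - mu2
    root1 = _sqrtm_psd(s1)
    covmean = _sqrtm_psd(root1 @ s2 @ root1)
    val = float(diff @ diff + np.trace(s1 + s2 - 2.0 * covmean))
    return max(val, 0.0)


def fid_std(real: EmbeddingSet, gen_batches: list[EmbeddingSet]) -> float:
    """Sample standard deviation of per-batch FIDs against the real set."""
    if len(gen_batches) < 2:
        raise ValueError("need at least 2 generated batches")
    vals = np.array([fid(real, g) for g in gen_batches])
    return float(vals.std(ddof=1))


def mse(i: np.ndarray, i_hat: np.ndarray) -> float:
    """Mean squared pixel difference."""
    i, i_hat = np.asarray(i, float), np.asarray(i_hat, float)
    if i.shape != i_hat.shape:
        raise ValueError(f"shape mismatch {i.shape} vs {i_hat.shape}")
    return float(np.mean((i - i_hat) ** 2))


def ssim(i: np.ndarray, i_hat: np.ndarray, L: float = 1.0,
         k1: float = 0.01, k2: float = 0.03, mode: str = "global",
         win_size: int = 7) -> float:
    """Structural similarity in [-1, 1].

    luminance/contrast/structure form:
        (2 mu_x mu_y + c1)(2 cov_xy + c2) /
        ((mu_x^2 + mu_y^2 + c1)(var_x + var_y + c2))
    with c1 = (k1 L)^2, c2 = (k2 L)^2 and L the declared dynamic range.
    ``global`` uses whole-image moments; ``windowed`` averages the statistic
    over every win_size x win_size sliding window (sample moments, ddof=1).
    """
    x, y = np.asarray(i, float), np.asarray(i_hat, float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    if L <= 0:
        raise ValueError("dynamic range L must be positive")
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2

    def stat(xs, ys, axis):
        n = np.prod([xs.shape[a] for a in axis])
        mx = xs.mean(axis=axis)
        my = ys.mean(axis=axis)
        vx = xs.var(axis=axis, ddof=1)
        vy = ys.var(axis=axis, ddof=1)
        cov = ((xs - np.expand_dims(mx, axis)) *
               (ys - np.expand_dims(my, axis))).sum(axis=axis) / (n - 1)
        return ((2 * mx * my + c1) * (2 * cov + c2)) / (
            (mx**2 + my**2 + c1) * (vx + vy + c2)
        )

    if mode == "global":
        return float(stat(x, y, axis=(0, 1)))
    if mode == "windowed":
        if min(x.shape) < win_size:
            raise ValueError("image smaller than the SSIM window")
        xw = np.lib.stride_tricks.sliding_window_view(x, (win_size, win_size))
        yw = np.lib.stride_tricks.sliding_window_view(y, (win_size, win_size))
        return float(stat(xw, yw, axis=(2, 3)).mean())
    raise ValueError(f"unknown SSIM mode {mode!r}")
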