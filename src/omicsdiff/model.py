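"""Model/Results front end for the conditional diffusion model.

``ConditionalDiffusionModel`` is built from data — a stack of square
grayscale images and a matching matrix of per-patient condition vectors —
plus a noise schedule and denoiser configuration.  ``fit()`` runs the
stochastic training loop and returns a ``DiffusionResults`` object carrying
the fitted parameters, the per-epoch loss trace, diagnostics, ``summary()``,
``sample()`` and ``evaluate()``.

Images may arrive in [0, 1] (the storage/metric range); training happens in
[-1, 1] and samples are mapped back to [0, 1] on the way out.
"""

from __future__ import annotations

import numpy as np

from . import diffusion, metrics
from .denoiser import ConditionalDenoiser, DenoiserConfig
from .nn import Adam
from .schedule import NoiseSchedule, make_schedule

__all__ = ["ConditionalDiffusionModel", "DiffusionResults"]


def _to_train_range(images: np.ndarray) -> np.ndarray:
    return images * 2.0 - 1.0


def _to_unit_range(images: np.ndarray) -> np.ndarray:
    return (images + 1.0) / 2.0


class ConditionalDiffusionModel:
    """Denoising diffusion model of 2D grayscale projections, conditioned on
    per-patient latent factor vectors.

    Parameters
    ----------
    images : (N, n, n) array in [0, 1]
        Training projections (one per patient).
    conditions : (N, R) array or None
        Condition vectors tau; ``None`` trains an unconditional model.
    schedule : NoiseSchedule, optional
        Defaults to a linear schedule with T=1000, beta 1e-4..0.02.
    config : DenoiserConfig, optional
        Defaults match the image size and condition dimension.
    """

    def __init__(self, images, conditions=None,
                 schedule: NoiseSchedule | None = None,
                 config: DenoiserConfig | None = None):
        images = np.asarray(images, float)
        if images.ndim != 3 or images.shape[1] != images.shape[2]:
            raise ValueError("images must be (N, n, n) with square frames")
        if images.min() < -1e-9 or images.max() > 1 + 1e-9:
            raise ValueError("images must be scaled to [0, 1]")
        self.images = images
        self.n = images.shape[1]
        if conditions is not None:
            conditions = np.asarray(conditions, float)
            if conditions.ndim != 2 or conditions.shape[0] != images.shape[0]:
                raise ValueError("need one condition vector per image")
        self.conditions = conditions
        self.schedule = schedule or make_schedule("linear", T=1000)
        r = 0 if conditions is None else conditions.shape[1]
        self.config = config or DenoiserConfig(
            image_size=self.n, cond_dim=max(r, 1)
        )
        if self.config.image_size != self.n:
            raise ValueError("config image_size does not match the data")
        if conditions is not None and self.config.cond_dim != r:
            raise ValueError("config cond_dim does not match the conditions")

    @classmethod
    def from_fixture(cls, spec, schedule=None, config=None):
        """Build directly from a synthetic FixtureSpec (paired phantom data)."""
        from .synthetic import make_paired_dataset

        factors, images, _ = make_paired_dataset(spec)
        return cls(images, factors.to_numpy(float), schedule=schedule,
                   config=config)

    def fit(self, epochs: int = 100, batch_size: int = 16, lr: float = 2e-3,
            seed: int = 0, log_every: int | None = None,
            callback=None) -> "DiffusionResults":
        """Train by stochastic gradient descent on the noise-prediction MSE.

        Returns a DiffusionResults; deterministic given ``seed`` (one root
        seed fans out to init / timestep / noise / shuffle streams).
        """
        streams = diffusion.SeedStreams(seed)
        denoiser = ConditionalDenoiser(self.config, streams.init)
        optimizer = Adam(denoiser.parameters(), lr=lr)
        x_train = _to_train_range(self.images)
        n = x_train.shape[0]
        epoch_losses = []
        for epoch in range(epochs):
            order = streams.shuffle.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                tau = None if self.conditions is None else self.conditions[idx]
                losses.append(diffusion.train_step(
                    x_train[idx], tau, denoiser, self.schedule, optimizer,
                    streams.t, streams.eps,
                ))
            epoch_losses.append(float(np.mean(losses)))
            if log_every and (epoch + 1) % log_every == 0:
                print(f"epoch {epoch + 1:4d}  loss {epoch_losses[-1]:.4f}")
            if callback is not None:
                callback(epoch, epoch_losses[-1])
        return DiffusionResults(self, denoiser, np.asarray(epoch_losses), seed)


class DiffusionResults:
    """Fitted conditional diffusion model: parameters, loss trace,
    generation and evaluation."""

    def __init__(self, model: ConditionalDiffusionModel,
                 denoiser: ConditionalDenoiser, loss_history: np.ndarray,
                 seed: int):
        self.model = model
        self.denoiser = denoiser
        self.loss_history = loss_history
        self.seed = seed

    @property
    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.denoiser.parameters()))

    @property
    def loss_reduction(self) -> float:
        """Fractional reduction of the epoch-mean loss from the first epoch."""
        first, last = self.loss_history[0], self.loss_history[-1]
        return float(1.0 - last / first) if first > 0 else 0.0

    def sample(self, conditions=None, n_images: int | None = None,
               seed: int = 0, sigma_scale: float = 1.0) -> np.ndarray:
        """Generate images for the given condition vectors (ancestral
        sampler); returns (n_images, n, n) arrays in [0, 1]."""
        if conditions is not None:
            conditions = np.atleast_2d(np.asarray(conditions, float))
            n_images = n_images or conditions.shape[0]
        elif n_images is None:
            n_images = 1
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, seed, 4]))
        out = diffusion.sample(
            conditions, self.denoiser, self.model.schedule, rng,
            (self.model.n, self.model.n), n_images=n_images,
            sigma_scale=sigma_scale,
        )
        return _to_unit_range(out)

    def evaluate(self, images=None, conditions=None, seed: int = 0,
                 n_fid_batches: int = 4, extractor: str = "pixels",
                 ssim_mode: str = "global") -> metrics.MetricsReport:
        """Generate one image per condition and score against the reference
        images (FID / FID-STD / mean MSE / mean SSIM, all in [0, 1] range).
        Defaults to the training set."""
        if images is None:
            images = self.model.images
            conditions = self.model.conditions
        images = np.asarray(images, float)
        gen = self.sample(conditions, n_images=images.shape[0], seed=seed)
        real_e = metrics.embed_images(images, extractor)
        gen_e = metrics.embed_images(gen, extractor)
        fid_val = metrics.fid(real_e, gen_e)
        fstd = None
        if images.shape[0] >= 2 * n_fid_batches >= 4:
            splits = np.array_split(np.arange(gen.shape[0]), n_fid_batches)
            batches = [metrics.embed_images(gen[s], extractor)
                       for s in splits if len(s) >= 2]
            if len(batches) >= 2:
                fstd = metrics.fid_std(real_e, batches)
        pair_mse = float(np.mean([metrics.mse(a, b) for a, b in zip(images, gen)]))
        pair_ssim = float(np.mean([
            metrics.ssim(a, b, L=1.0, mode=ssim_mode) for a, b in zip(images, gen)
        ]))
        return metrics.MetricsReport(
            fid=fid_val, fid_std=fstd, mse=pair_mse, ssim=pair_ssim,
            meta={"n_images": int(images.shape[0]), "extractor": extractor,
                  "ssim_mode": ssim_mode},
        )

    def summary(self) -> str:
        """Plain-text fit summary table."""
        m = self.model
        sch = m.schedule
        lines = [
            "Conditional Diffusion Model Results",
            "=" * 46,
            f"{'images':<28}{m.images.shape[0]:>6} x {m.n}x{m.n}",
            f"{'condition dim (R)':<28}{0 if m.conditions is None else m.conditions.shape[1]:>6}",
            f"{'timesteps T':<28}{sch.T:>6}",
            f"{'beta range':<28}{sch.beta[1]:>10.2e} .. {sch.beta[-1]:.2e}",
            f"{'sigma mode':<28}{sch.sigma_mode:>10}",
            f"{'parameters':<28}{self.n_params:>6}",
            f"{'epochs':<28}{len(self.loss_history):>6}",
            f"{'first-epoch loss':<28}{self.loss_history[0]:>10.4f}",
            f"{'final-epoch loss':<28}{self.loss_history[-1]:>10.4f}",
            f"{'loss reduction':<28}{100 * self.loss_reduction:>9.1f}%",
            f"{'root seed':<28}{self.seed:>6}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        self.denoiser.save(path, extra={
            "loss_history": list(map(float, self.loss_history)),
            "seed": self.seed,
            "schedule": {
                "T": self.model.schedule.T,
                "beta_start": float(self.model.schedule.beta[1]),
                "beta_end": float(self.model.schedule.beta[-1]),
                "sigma_mode": self.model.schedule.sigma_mode,
            },
        })
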