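"""Training and ancestral sampling for the conditional diffusion model.

Training draws a timestep t ~ Uniform{1..T} and noise eps ~ N(0, I) per
item, jumps to x_t with the closed form, asks the denoiser for eps_hat from
the condition-fused noisy input, and descends the simplified objective
||eps - eps_hat||^2.  Sampling starts from pure noise x_T ~ N(0, I) and
iterates

    x_{t-1} = (x_t - (1-alpha_t)/sqrt(1-alpha_bar_t) eps_theta(x_t,t,tau))
              / sqrt(alpha_t) + sigma_t z,       z = 0 at t = 1,

returning x_0 clipped to the training value range [-1, 1].

One root seed fans out to independent per-purpose generators (timestep
draws, training noise, sampler noise, parameter init) via SeedSequence
spawning, so runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .denoiser import ConditionalDenoiser
from .schedule import NoiseSchedule, forward_sample, training_loss

__all__ = ["SeedStreams", "train_step", "sample", "TrainingError", "SamplingError"]


class TrainingError(RuntimeError):
    pass


class SamplingError(RuntimeError):
    pass


class SeedStreams:
    """Per-purpose random generators derived from one root seed."""

    PURPOSES = ("init", "t", "eps", "z", "shuffle")

    def __init__(self, root_seed: int):
        self.root_seed = int(root_seed)
        children = np.random.SeedSequence(self.root_seed).spawn(len(self.PURPOSES))
        for name, ss in zip(self.PURPOSES, children):
            setattr(self, name, np.random.default_rng(ss))


def train_step(
    x0: np.ndarray,
    tau: np.ndarray | None,
    denoiser: ConditionalDenoiser,
    schedule: NoiseSchedule,
    optimizer: nn.Adam,
    rng_t: np.random.Generator,
    rng_eps: np.random.Generator,
) -> float:
    """One stochastic gradient step on a batch; returns the loss value.

    ``x0``: (B, n, n) images in [-1, 1]; ``tau``: (B, R) condition vectors.
    """
    x0 = np.asarray(x0, float)
    b = x0.shape[0]
    t = rng_t.integers(1, schedule.T + 1, size=b)
    eps = rng_eps.standard_normal(x0.shape)
    x_t = forward_sample(x0, t, eps, schedule)

    eps_hat = denoiser.predict_noise(x_t, t, tau)
    target = nn.Tensor(eps.reshape(eps_hat.shape))
    loss = ((eps_hat - target) ** 2).mean()
    if not np.isfinite(loss.value):
        raise TrainingError(
            f"non-finite loss at t={t.tolist()}; check schedule and learning rate"
        )
    optimizer.zero_grad()
    loss.backward()
    optimizer.step()
    return float(loss.value)


def sample(
    tau: np.ndarray | None,
    denoiser: ConditionalDenoiser,
    schedule: NoiseSchedule,
    rng_z: np.random.Generator,
    shape: tuple[int, int],
    n_images: int = 1,
    sigma_scale: float = 1.0,
    x_init: np.ndarray | None = None,
) -> np.ndarray:
    """Ancestral sampling; returns (n_images, n, n) arrays clipped to [-1, 1].

    ``tau`` may be None (unconditional), a single R-vector shared by all
    images, or an (n_images, R) matrix.  ``sigma_scale=0`` runs the
    deterministic trajectory (no injected noise at any step); ``x_init``
    overrides the N(0, I) starting state x_T.
    """
    n, m = shape
    if tau is not None:
        tau = np.atleast_2d(np.asarray(tau, float))
        if tau.shape[0] == 1 and n_images > 1:
            tau = np.repeat(tau, n_images, axis=0)
        if tau.shape[0] != n_images:
            raise ValueError("need one condition vector per image")
    if x_init is not None:
        x = np.asarray(x_init, float).reshape(n_images, n, m).copy()
    else:
        x = rng_z.standard_normal((n_images, n, m))
    for t in range(schedule.T, 0, -1):
        eps_hat = denoiser.predict_noise(x, t, tau).value.reshape(x.shape)
        a = schedule.alpha[t]
        abar = schedule.alpha_bar[t]
        x = (x - (1.0 - a) / np.sqrt(1.0 - abar) * eps_hat) / np.sqrt(a)
        if t > 1 and sigma_scale > 0.0:
            x = x + sigma_scale * schedule.sigma[t] * rng_z.standard_normal(x.shape)
        if not np.all(np.isfinite(x)):
            raise SamplingError(f"non-finite sample at t={t}")
    return np.clip(x, -1.0, 1.0)
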