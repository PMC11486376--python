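"""Noise schedule and the closed-form algebra of Gaussian diffusion.

The forward process is the Markov chain
``q(x_t | x_{t-1}) = N(x_t; sqrt(1-beta_t) x_{t-1}, beta_t I)`` with a
variance schedule ``0 < beta_1 <= ... <= beta_T < 1``.  Writing
``alpha_t = 1 - beta_t`` and ``alpha_bar_t = prod_{i<=t} alpha_i`` gives the
closed form ``x_t = sqrt(alpha_bar_t) x_0 + sqrt(1-alpha_bar_t) eps`` and a
Gaussian reverse conditional ``q(x_{t-1}|x_t,x_0)`` with variance
``beta_tilde_t = (1-alpha_bar_{t-1})/(1-alpha_bar_t) beta_t``.

Timesteps are 1-based (t in 1..T); the convention ``alpha_bar_0 := 1`` makes
every formula total at t=1.  Arrays are stored with index 0 as that boundary
slot, so ``schedule.alpha_bar[t]`` is mathematically alpha-bar at step t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoiseSchedule",
    "make_schedule",
    "forward_sample",
    "single_step_forward",
    "posterior_mean",
    "posterior_mean_from_eps",
    "posterior_variance",
    "predict_x0",
    "training_loss",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseSchedule:
    """Per-timestep scalars of the diffusion process (1-based, slot 0 = boundary).

    sigma is the ancestral-sampler noise scale: sigma_t^2 = beta_t by default
    ("beta" mode) or the posterior variance beta_tilde_t ("beta_tilde" mode).
    """

    T: int
    beta: np.ndarray        # beta[0] = 0 (unused), beta[1..T]
    alpha: np.ndarray       # 1 - beta
    alpha_bar: np.ndarray   # cumulative product, alpha_bar[0] = 1
    beta_tilde: np.ndarray  # posterior variance, beta_tilde[1] = 0
    sigma: np.ndarray
    sigma_mode: str = "beta"

    def __post_init__(self):
        b = self.beta[1:]
        if np.any(b <= 0) or np.any(b >= 1):
            raise ConfigError("beta must lie strictly inside (0, 1)")
        if np.any(np.diff(b) < 0):
            raise ConfigError("beta must be non-decreasing")
        if np.any(np.diff(self.alpha_bar) >= 0):
            raise ConfigError("alpha_bar must be strictly decreasing")

    def check_t(self, t) -> np.ndarray:
        t = np.asarray(t)
        if np.any(t < 1) or np.any(t > self.T):
            raise ValueError(f"timestep out of range [1, {self.T}]: {t}")
        return t


def make_schedule(
    kind: str = "linear",
    T: int = 1000,
    beta_start: float = 1e-4,
    beta_end: float = 0.02,
    sigma_mode: str = "beta",
) -> NoiseSchedule:
    """Build a noise schedule with all derived per-timestep scalars.

    ``kind='linear'`` interpolates beta from beta_start to beta_end;
    ``kind='cosine'`` uses the squared-cosine alpha-bar profile with betas
    clipped into (0, 0.999], which keeps them non-decreasing and bounded.
    """
    if T < 1:
        raise ConfigError("T must be >= 1")
    if not (0 < beta_start <= beta_end < 1):
        raise ConfigError("need 0 < beta_start <= beta_end < 1")
    if sigma_mode not in ("beta", "beta_tilde"):
        raise ConfigError(f"unknown sigma_mode {sigma_mode!r}")

    if kind == "linear":
        betas = np.linspace(beta_start, beta_end, T)
    elif kind == "cosine":
        s = 0.008
        steps = np.arange(T + 1)
        f = np.cos((steps / T + s) / (1 + s) * np.pi / 2) ** 2
        abar = f / f[0]
        betas = np.clip(1 - abar[1:] / abar[:-1], 1e-8, 0.999)
        betas = np.maximum.accumulate(betas)
    else:
        raise ConfigError(f"unknown schedule kind {kind!r}")

    beta = np.concatenate([[0.0], betas])
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    alpha_bar[0] = 1.0
    beta_tilde = np.zeros(T + 1)
    beta_tilde[1:] = (1.0 - alpha_bar[:-1]) / (1.0 - alpha_bar[1:]) * beta[1:]
    sigma = np.sqrt(beta if sigma_mode == "beta" else beta_tilde)
    return NoiseSchedule(
        T=T, beta=beta, alpha=alpha, alpha_bar=alpha_bar,
        beta_tilde=beta_tilde, sigma=sigma, sigma_mode=sigma_mode,
    )


def _bcast(arr: np.ndarray, t, like: np.ndarray) -> np.ndarray:
    """Gather per-timestep scalars for t (scalar or per-item) and shape them
    for broadcasting against a batch of images."""
    v = arr[np.asarray(t)]
    if v.ndim == 0:
        return v
    return v.reshape((-1,) + (1,) * (np.asarray(like).ndim - 1))


def forward_sample(x0, t, eps, schedule: NoiseSchedule):
    """Closed-form jump to step t: x_t = sqrt(abar_t) x0 + sqrt(1-abar_t) eps."""
    schedule.check_t(t)
    abar = _bcast(schedule.alpha_bar, t, x0)
    return np.sqrt(abar) * np.asarray(x0) + np.sqrt(1.0 - abar) * np.asarray(eps)


def single_step_forward(x_prev, t, eps, schedule: NoiseSchedule):
    """One Markov step: x_t = sqrt(1-beta_t) x_{t-1} + sqrt(beta_t) eps."""
    schedule.check_t(t)
    b = _bcast(schedule.beta, t, x_prev)
    return np.sqrt(1.0 - b) * np.asarray(x_prev) + np.sqrt(b) * np.asarray(eps)


def posterior_variance(t, schedule: NoiseSchedule):
    """Variance of q(x_{t-1} | x_t, x_0); zero at t=1 by the abar_0=1 convention."""
    schedule.check_t(t)
    return schedule.beta_tilde[np.asarray(t)]


def posterior_mean(x_t, x0, t, schedule: NoiseSchedule):
    """Mean of q(x_{t-1} | x_t, x_0):

    mu = [sqrt(alpha_t)(1-abar_{t-1}) x_t + sqrt(abar_{t-1}) beta_t x_0] / (1-abar_t)
    """
    t = schedule.check_t(t)
    a = _bcast(schedule.alpha, t, x_t)
    abar_prev = _bcast(schedule.alpha_bar, t - 1, x_t)
    abar = _bcast(schedule.alpha_bar, t, x_t)
    b = _bcast(schedule.beta, t, x_t)
    return (
        np.sqrt(a) * (1.0 - abar_prev) * np.asarray(x_t)
        + np.sqrt(abar_prev) * b * np.asarray(x0)
    ) / (1.0 - abar)


def posterior_mean_from_eps(x_t, eps, t, schedule: NoiseSchedule):
    """Equivalent noise parameterisation of the posterior mean:

    mu = (x_t - (1-alpha_t)/sqrt(1-abar_t) eps) / sqrt(alpha_t)
    """
    t = schedule.check_t(t)
    a = _bcast(schedule.alpha, t, x_t)
    abar = _bcast(schedule.alpha_bar, t, x_t)
    return (np.asarray(x_t) - (1.0 - a) / np.sqrt(1.0 - abar) * np.asarray(eps)) / np.sqrt(a)


def predict_x0(x_t, eps, t, schedule: NoiseSchedule):
    """Invert the closed form: x0 = (x_t - sqrt(1-abar_t) eps) / sqrt(abar_t)."""
    schedule.check_t(t)
    abar = _bcast(schedule.alpha_bar, t, x_t)
    return (np.asarray(x_t) - np.sqrt(1.0 - abar) * np.asarray(eps)) / np.sqrt(abar)


def training_loss(eps, eps_hat) -> float:
    """Mean squared error between true and predicted noise (the simplified
    denoising objective)."""
    eps = np.asarray(eps)
    eps_hat = np.asarray(eps_hat)
    if eps.shape != eps_hat.shape:
        raise ValueError(f"shape mismatch {eps.shape} vs {eps_hat.shape}")
    return float(np.mean((eps - eps_hat) ** 2))
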