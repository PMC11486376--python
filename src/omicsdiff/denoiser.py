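"""The noise-prediction network eps_theta(NI, t, tau).

A small shape-preserving U-Net: per-stage conv blocks (3x3 conv, group norm,
additive time-embedding bias, SiLU gating), 2x average-pool downsampling,
nearest-neighbour upsampling with skip concatenation, and cross-attention to
the omics condition tokens at the bottleneck.  ``ConditionalDenoiser``
bundles the U-Net with the input-resolution inner-product fusion so a single
object maps (noisy image P, timestep t, condition tau) to predicted noise.

Capacity defaults (depth 3, base 32 channels, multipliers 1/2/4) are sized
so a 16x16 model trains on one CPU in minutes; everything is configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .conditioning import ConditionExtension, CrossAttention
from .nn import Tensor

__all__ = ["DenoiserConfig", "UNet", "ConditionalDenoiser", "time_embed"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DenoiserConfig:
    image_size: int = 128
    cond_dim: int = 17            # R, length of the latent factor vector tau
    base_channels: int = 32
    depth: int = 3
    channel_mults: tuple = (1, 2, 4)
    blocks_per_stage: int = 2
    time_embed_dim: int = 64
    groups: int = 4
    n_cond_tokens: int = 4
    n_heads: int = 1
    bottleneck_attention: bool = True
    extension: str = "dense"
    gate_init: float = 0.0
    tau_in_time_embed: bool = True  # per-stage condition pathway (ablation flag)

    def __post_init__(self):
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        if len(self.channel_mults) != self.depth:
            raise ConfigError("need one channel multiplier per stage")
        if self.image_size % (2**self.depth) != 0:
            raise ConfigError(
                f"image size {self.image_size} not divisible by 2^depth={2**self.depth}"
            )
        if self.time_embed_dim % 2 != 0:
            raise ConfigError("time_embed_dim must be even")


def time_embed(t, dim: int, T: int | None = None) -> np.ndarray:
    """Sinusoidal timestep embedding.

    Components come in (sin, cos) pairs: emb[2i] = sin(t * w_i),
    emb[2i+1] = cos(t * w_i) with w_i = 10000^(-2i/dim), so w_0 = 1.
    Injective over integer t in [1, T] for dim >= 2.
    """
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    if np.any(t < 1):
        raise ValueError("timestep must be >= 1")
    if T is not None and np.any(t > T):
        raise ValueError(f"timestep above T={T}")
    half = dim // 2
    omega = 10000.0 ** (-2.0 * np.arange(half) / dim)
    ang = t[:, None] * omega[None, :]
    emb = np.empty((t.shape[0], dim))
    emb[:, 0::2] = np.sin(ang)
    emb[:, 1::2] = np.cos(ang)
    return emb


class ConvBlock(nn.Module):
    """conv3x3 -> group norm -> + time bias -> SiLU."""

    def __init__(self, c_in: int, c_out: int, t_dim: int, groups: int,
                 rng: np.random.Generator):
        self.conv = nn.Conv2d(c_in, c_out, 3, rng)
        self.norm = nn.GroupNorm(min(groups, c_out), c_out)
        self.time = nn.Linear(t_dim, c_out, rng)
        self.c_out = c_out

    def __call__(self, x: Tensor, temb: Tensor) -> Tensor:
        h = self.norm(self.conv(x))
        bias = self.time(temb).reshape(x.shape[0], self.c_out, 1, 1)
        return nn.silu(h + bias)


class UNet(nn.Module):
    """Shape-preserving denoiser; ``denoise(NI, t, tau)`` returns eps_hat."""

    def __init__(self, config: DenoiserConfig, rng: np.random.Generator):
        self.config = config
        c = config
        tdim = c.time_embed_dim
        chans = [c.base_channels * m for m in c.channel_mults]

        self.time_mlp1 = nn.Linear(tdim, tdim, rng)
        self.time_mlp2 = nn.Linear(tdim, tdim, rng)
        self.tau_time = (
            nn.Linear(c.cond_dim, tdim, rng) if c.tau_in_time_embed else None
        )

        self.stem = nn.Conv2d(1, chans[0], 3, rng)
        self.down_blocks = []
        prev = chans[0]
        for ch in chans:
            stage = [ConvBlock(prev if i == 0 else ch, ch, tdim, c.groups, rng)
                     for i in range(c.blocks_per_stage)]
            self.down_blocks.append(stage)
            prev = ch

        self.mid1 = ConvBlock(prev, prev, tdim, c.groups, rng)
        self.attn = (
            CrossAttention(c.cond_dim, prev, rng, n_tokens=c.n_cond_tokens,
                           n_heads=c.n_heads)
            if c.bottleneck_attention else None
        )
        self.mid2 = ConvBlock(prev, prev, tdim, c.groups, rng)

        self.up_blocks = []
        up_prev = prev
        for ch in reversed(chans):
            stage = [ConvBlock(up_prev + ch if i == 0 else ch, ch, tdim,
                               c.groups, rng)
                     for i in range(c.blocks_per_stage)]
            self.up_blocks.append(stage)
            up_prev = ch
        self.head = nn.Conv2d(chans[0], 1, 3, rng)
        # keep the untrained prediction small so early sampling stays finite
        self.head.w.value *= 0.1

    # registered lists of Modules are not auto-discovered through nesting in
    # plain lists of lists, so flatten explicitly
    def _collect(self, params, seen):
        super()._collect(params, seen)
        for stage in self.down_blocks + self.up_blocks:
            for block in stage:
                block._collect(params, seen)

    def _temb(self, t, tau: Tensor | None) -> Tensor:
        base = Tensor(time_embed(t, self.config.time_embed_dim))
        h = nn.silu(self.time_mlp1(base))
        h = self.time_mlp2(h)
        if self.tau_time is not None and tau is not None:
            h = h + self.tau_time(tau)
        return h

    def denoise(self, ni: Tensor | np.ndarray, t, tau: Tensor | np.ndarray | None) -> Tensor:
        if not isinstance(ni, Tensor):
            ni = Tensor(ni)
        if tau is not None and not isinstance(tau, Tensor):
            tau = Tensor(np.atleast_2d(np.asarray(tau, float)))
        b = ni.shape[0]
        t = np.broadcast_to(np.asarray(t), (b,))
        temb = self._temb(t, tau)

        h = self.stem(ni)
        skips = []
        for stage in self.down_blocks:
            for block in stage:
                h = block(h, temb)
            skips.append(h)
            h = nn.avg_pool2d(h)
        h = self.mid1(h, temb)
        if self.attn is not None and tau is not None:
            h = self.attn(h, tau)
        h = self.mid2(h, temb)
        for stage in self.up_blocks:
            h = nn.upsample_nearest2d(h)
            h = nn.concat([h, skips.pop()], axis=1)
            for block in stage:
                h = block(h, temb)
        return self.head(h)


class ConditionalDenoiser(nn.Module):
    """Inner-product condition fusion + U-Net, as one trainable unit.

    ``predict_noise(P, t, tau)`` forms NI = P + gate * (F(tau) @ P) at the
    input resolution and runs the U-Net on it.
    """

    def __init__(self, config: DenoiserConfig, rng: np.random.Generator):
        self.config = config
        self.extension = ConditionExtension(
            config.cond_dim, config.image_size, rng,
            gate_init=config.gate_init, mode=config.extension,
        )
        self.unet = UNet(config, rng)

    def predict_noise(self, p: Tensor | np.ndarray, t,
                      tau: Tensor | np.ndarray | None) -> Tensor:
        if not isinstance(p, Tensor):
            p = Tensor(np.asarray(p, float))
        if p.ndim == 2:
            p = p.reshape(1, 1, *p.shape)
        elif p.ndim == 3:
            p = p.reshape(p.shape[0], 1, p.shape[1], p.shape[2])
        if tau is not None:
            if not isinstance(tau, Tensor):
                tau = Tensor(np.atleast_2d(np.asarray(tau, float)))
            ni = self.extension.fuse(p, tau)
        else:
            ni = p
        return self.unet.denoise(ni, t, tau)

    # -- checkpointing -----------------------------------------------------
    def save(self, path, extra: dict | None = None) -> None:
        """Serialize config + parameters (and optional metadata) to .npz."""
        cfg = asdict(self.config)
        cfg["channel_mults"] = list(cfg["channel_mults"])
        meta = {"config": cfg, "extra": extra or {}}
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> tuple["ConditionalDenoiser", dict]:
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            arrays = [data[f"p{i}"] for i in range(len(data.files) - 1)]
        cfg = meta["config"]
        cfg["channel_mults"] = tuple(cfg["channel_mults"])
        model = cls(DenoiserConfig(**cfg), np.random.default_rng(0))
        model.load_state_arrays(arrays)
        return model, meta["extra"]
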