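"""Fusing the per-patient omics condition vector with image-space data.

Two mechanisms steer generation:

* **Inner-product fusion** at the input resolution: the condition vector tau
  (R latent factor scores) is linearly extended to an n x n map F, the matrix
  product X = F @ P with the noisy image P is formed, and the noisy input
  NI = P + X is what the denoiser sees.  A learnable scalar gate (init 0)
  scales X so training starts from the unconditional model.

* **Cross-attention** at the U-Net bottleneck: queries come from the omics
  side (condition tokens), keys/values from the image side (flattened
  bottleneck positions), A = softmax(Q_A K_B^T / sqrt(d_k)), WV = A V_B, and
  the fused representation FR = WV W_OB is folded back into the feature map.

Each operation has a plain-ndarray functional form (used by the algebra
tests) and a trainable ``nn.Module`` counterpart sharing the same math.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "AttentionParams",
    "extend_linear",
    "inner_product_fuse",
    "noisy_input",
    "cross_attention",
    "ConditionExtension",
    "CrossAttention",
]


@dataclass
class AttentionParams:
    """Projection matrices for single-head cross-attention.

    w_qa: (d_a, d_k) queries from the condition side
    w_kb: (d_b, d_k) keys from the image side
    w_vb: (d_b, d_v) values from the image side
    w_ob: (d_v, d_out) output projection
    """

    w_qa: np.ndarray
    w_kb: np.ndarray
    w_vb: np.ndarray
    w_ob: np.ndarray

    def __post_init__(self):
        if self.w_qa.shape[1] != self.w_kb.shape[1]:
            raise ValueError("query and key projections must share d_k")
        if self.w_vb.shape[1] != self.w_ob.shape[0]:
            raise ValueError("value and output projections are incompatible")

    @property
    def d_k(self) -> int:
        return self.w_qa.shape[1]


def _attention_t(xa: Tensor, xb: Tensor, wq: Tensor, wk: Tensor,
                 wv: Tensor, wo: Tensor, d_k: int):
    """Tensor-graph cross-attention; returns (FR, A)."""
    q = xa @ wq
    k = xb @ wk
    v = xb @ wv
    logits = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) * (
        1.0 / np.sqrt(d_k)
    )
    attn = nn.softmax(logits, axis=-1)
    return (attn @ v) @ wo, attn


def cross_attention(x_a: np.ndarray, x_b: np.ndarray, params: AttentionParams,
                    return_weights: bool = False):
    """Attend from condition tokens ``x_a`` (N_A x d_a) to image tokens
    ``x_b`` (N_B x d_b); returns the fused representation FR (N_A x d_out).

    Every row of the attention matrix is a softmax, hence sums to 1 and lies
    elementwise in (0, 1); logits are max-stabilised before exponentiation.
    """
    x_a, x_b = np.asarray(x_a, float), np.asarray(x_b, float)
    if x_a.shape[-1] != params.w_qa.shape[0] or x_b.shape[-1] != params.w_kb.shape[0]:
        raise ValueError("token feature dimensions do not match the projections")
    fr, attn = _attention_t(
        Tensor(x_a), Tensor(x_b),
        Tensor(params.w_qa), Tensor(params.w_kb),
        Tensor(params.w_vb), Tensor(params.w_ob),
        params.d_k,
    )
    if not np.all(np.isfinite(attn.value)):
        raise FloatingPointError("non-finite attention weights")
    if return_weights:
        return fr.value, attn.value
    return fr.value


def extend_linear(tau: np.ndarray, weight: np.ndarray, bias: np.ndarray | None,
                  n: int) -> np.ndarray:
    """Linearly extend an R-vector tau to an n x n map: F = reshape(tau W + b).

    ``weight`` is (R, n*n); with zero bias the map is exactly linear in tau.
    """
    tau = np.asarray(tau, float)
    if weight.shape != (tau.shape[-1], n * n):
        raise ValueError(f"extension weight must be ({tau.shape[-1]}, {n * n})")
    out = tau @ weight
    if bias is not None:
        out = out + bias
    return out.reshape(tau.shape[:-1] + (n, n))


def inner_product_fuse(f: np.ndarray, p: np.ndarray) -> np.ndarray:
    """X = F @ P, the matrix product of the extended condition map with the
    image; bilinear in (F, P)."""
    f, p = np.asarray(f, float), np.asarray(p, float)
    if f.shape[-1] != p.shape[-2] or f.shape[-2:] != p.shape[-2:]:
        raise ValueError(f"F and P must be equal-sized square matrices, got {f.shape} and {p.shape}")
    return f @ p

def noisy_input(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    """NI = P + X: add the fused interaction map back onto the noisy image."""
    p, x = np.asarray(p, float), np.asarray(x, float)
    if p.shape != x.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {x.shape}")
    return p + x


class ConditionExtension(nn.Module):
    """Learnable linear extension of tau to an n x n map, with a scalar gate
    (init 0).

    ``mode='dense'`` uses a full R -> n^2 map; ``mode='outer'`` maps tau to
    two n-vectors u, v and completes F = u v^T (n^2 entries from 2n
    parameters per factor).  ``fuse(P, tau)`` returns
    NI = P + gate * (F(tau) @ P) for image batches (B, 1, n, n); with the
    gate at 0 this is the unconditional identity.
    """

    def __init__(self, r: int, n: int, rng: np.random.Generator,
                 weight_scale: float = 0.01, gate_init: float = 0.0,
                 mode: str = "dense"):
        if mode not in ("dense", "outer"):
            raise ValueError(f"unknown extension mode {mode!r}")
        self.n = n
        self.mode = mode
        if mode == "dense":
            self.weight = Tensor(rng.normal(0.0, weight_scale, (r, n * n)),
                                 requires_grad=True)
            self.bias = Tensor(np.zeros(n * n), requires_grad=True)
        else:
            self.w_u = Tensor(rng.normal(0.0, weight_scale, (r, n)),
                              requires_grad=True)
            self.w_v = Tensor(rng.normal(0.0, weight_scale, (r, n)),
                              requires_grad=True)
        self.gate = Tensor(np.array(float(gate_init)), requires_grad=True)

    def extend(self, tau: Tensor) -> Tensor:
        b = tau.shape[0]
        if self.mode == "dense":
            return (tau @ self.weight + self.bias).reshape(b, self.n, self.n)
        u = (tau @ self.w_u).reshape(b, self.n, 1)
        v = (tau @ self.w_v).reshape(b, 1, self.n)
        return u @ v

    def fuse(self, p: Tensor, tau: Tensor) -> Tensor:
        b = p.shape[0]
        f = self.extend(tau)
        x = f @ p.reshape(b, self.n, self.n)
        return p + (self.gate * x).reshape(b, 1, self.n, self.n)


class CrossAttention(nn.Module):
    """Bottleneck cross-attention: lifts tau to a small set of condition
    tokens, attends from them to the flattened spatial positions, and returns
    a per-channel bias (token-averaged FR) added to the feature map through a
    zero-initialised gate.  ``n_heads`` splits the key/value dimension into
    independent heads whose outputs are concatenated before W_OB."""

    def __init__(self, r: int, channels: int, rng: np.random.Generator,
                 n_tokens: int = 4, n_heads: int = 1):
        if n_tokens < 1:
            raise ValueError("need at least one condition token")
        if n_heads < 1 or channels % n_heads != 0:
            raise ValueError("head count must divide the channel dimension")
        self.n_tokens = n_tokens
        self.n_heads = n_heads
        self.d_k = channels // n_heads
        self.lift = nn.Linear(r, n_tokens * channels, rng)
        self.channels = channels
        s = 1.0 / np.sqrt(channels)
        d = self.d_k
        self.w_qa = [Tensor(rng.normal(0, s, (channels, d)), requires_grad=True)
                     for _ in range(n_heads)]
        self.w_kb = [Tensor(rng.normal(0, s, (channels, d)), requires_grad=True)
                     for _ in range(n_heads)]
        self.w_vb = [Tensor(rng.normal(0, s, (channels, d)), requires_grad=True)
                     for _ in range(n_heads)]
        self.w_ob = Tensor(rng.normal(0, s, (channels, channels)), requires_grad=True)
        self.gate = Tensor(np.array(0.0), requires_grad=True)

    def __call__(self, h: Tensor, tau: Tensor) -> Tensor:
        b, c, hh, ww = h.shape
        tokens_img = h.reshape(b, c, hh * ww).transpose(0, 2, 1)  # (B, HW, C)
        tokens_cond = self.lift(tau).reshape(b, self.n_tokens, c)
        heads = []
        for i in range(self.n_heads):
            q = tokens_cond @ self.w_qa[i]
            k = tokens_img @ self.w_kb[i]
            v = tokens_img @ self.w_vb[i]
            logits = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(self.d_k))
            heads.append(nn.softmax(logits, axis=-1) @ v)
        wv = heads[0] if self.n_heads == 1 else nn.concat(heads, axis=-1)
        fr = wv @ self.w_ob
        bias = fr.mean(axis=1)  # (B, C); invariant to image-token order
        return h + (self.gate * bias).reshape(b, c, 1, 1)
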