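"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The denoising network is small (tens of thousands of parameters, 16-128 px
inputs), so a tape-based engine over float64 ndarrays is fast enough on one
CPU and keeps the whole training stack dependency-free.  Only the operations
the U-Net and its conditioning layers need are implemented: broadcasting
arithmetic, matmul, reductions, 3x3 "same" convolution via im2col, 2x
average-pool / nearest-upsample, concatenation, SiLU/sigmoid/exp/log and a
numerically stabilised softmax.

Gradients of every primitive are exercised against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Module",
    "Linear",
    "Conv2d",
    "GroupNorm",
    "Adam",
    "concat",
    "softmax",
    "silu",
    "sigmoid",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing over broadcast axes."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph.

    ``value`` is always a float64 ndarray.  Leaf tensors created with
    ``requires_grad=True`` accumulate into ``.grad`` on ``backward()``.
    """

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_vjps")

    def __init__(self, value, requires_grad: bool = False, parents=(), vjps=()):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._vjps = vjps

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # -- graph construction ------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def detach(self) -> "Tensor":
        return Tensor(self.value)

    # arithmetic
    def __add__(self, other):
        other = self._lift(other)
        return Tensor(
            self.value + other.value,
            parents=(self, other),
            vjps=(
                lambda g: _unbroadcast(g, self.shape),
                lambda g: _unbroadcast(g, other.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, parents=(self,), vjps=(lambda g: -g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        return Tensor(
            self.value * other.value,
            parents=(self, other),
            vjps=(
                lambda g: _unbroadcast(g * other.value, self.shape),
                lambda g: _unbroadcast(g * self.value, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return Tensor(
            self.value / other.value,
            parents=(self, other),
            vjps=(
                lambda g: _unbroadcast(g / other.value, self.shape),
                lambda g: _unbroadcast(-g * self.value / other.value**2, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)
        return Tensor(
            self.value**p,
            parents=(self,),
            vjps=(lambda g: g * p * self.value ** (p - 1),),
        )

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self.value, other.value

        def vjp_a(g):
            ga = g @ np.swapaxes(b, -1, -2)
            return _unbroadcast(ga, self.shape)

        def vjp_b(g):
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(gb, other.shape)

        return Tensor(a @ b, parents=(self, other), vjps=(vjp_a, vjp_b))

    # shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor(
            self.value.reshape(shape),
            parents=(self,),
            vjps=(lambda g: g.reshape(old),),
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return Tensor(
            self.value.transpose(axes),
            parents=(self,),
            vjps=(lambda g: g.transpose(inv),),
        )

    # reductions
    def sum(self, axis=None, keepdims=False):
        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, self.shape).copy()
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                for a in sorted(a % self.ndim for a in ax):
                    g = np.expand_dims(g, a)
            return np.broadcast_to(g, self.shape).copy()

        return Tensor(
            self.value.sum(axis=axis, keepdims=keepdims), parents=(self,), vjps=(vjp,)
        )

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # elementwise nonlinearities
    def exp(self):
        out = np.exp(self.value)
        return Tensor(out, parents=(self,), vjps=(lambda g: g * out,))

    def log(self):
        return Tensor(
            np.log(self.value), parents=(self,), vjps=(lambda g: g / self.value,)
        )

    def sqrt(self):
        out = np.sqrt(self.value)
        return Tensor(out, parents=(self,), vjps=(lambda g: g * 0.5 / out,))

    # -- backprop ----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, vjp in zip(node._parents, node._vjps):
                if not parent.requires_grad:
                    continue
                pg = vjp(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                elif parent._parents:
                    grads[id(parent)] = pg
                else:
                    parent.grad = pg if parent.grad is None else parent.grad + pg


# -- free functions --------------------------------------------------------


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.value))
    return Tensor(s, parents=(x,), vjps=(lambda g: g * s * (1.0 - s),))


def silu(x: Tensor) -> Tensor:
    """x * sigmoid(x), the smooth gating nonlinearity used in the conv blocks."""
    s = 1.0 / (1.0 + np.exp(-x.value))
    out = x.value * s
    return Tensor(out, parents=(x,), vjps=(lambda g: g * (s + out * (1.0 - s)),))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Row-softmax with max-subtraction stabilisation (max treated as constant)."""
    shifted = x - Tensor(x.value.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def make_vjp(i):
        return lambda g: np.split(g, splits, axis=axis)[i]

    return Tensor(
        np.concatenate([t.value for t in tensors], axis=axis),
        parents=tuple(tensors),
        vjps=tuple(make_vjp(i) for i in range(len(tensors))),
    )


def avg_pool2d(x: Tensor) -> Tensor:
    """2x2 average pooling on (B, C, H, W)."""
    b, c, h, w = x.shape
    out = x.value.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def vjp(g):
        g = g[:, :, :, None, :, None] / 4.0
        return np.broadcast_to(g, (b, c, h // 2, 2, w // 2, 2)).reshape(b, c, h, w)

    return Tensor(out, parents=(x,), vjps=(vjp,))


def upsample_nearest2d(x: Tensor) -> Tensor:
    """2x nearest-neighbour upsampling on (B, C, H, W)."""
    b, c, h, w = x.shape
    out = np.repeat(np.repeat(x.value, 2, axis=2), 2, axis=3)

    def vjp(g):
        return g.reshape(b, c, h, 2, w, 2).sum(axis=(3, 5))

    return Tensor(out, parents=(x,), vjps=(vjp,))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """'Same' convolution of (B, C, H, W) with (O, C, k, k), stride 1, odd k."""
    bs, c, h, wd = x.shape
    o, _, k, _ = w.shape
    pad = k // 2
    xp = np.pad(x.value, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    # cols: (B, C*k*k, H*W)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(bs, c * k * k, h * wd)
    w2 = w.value.reshape(o, c * k * k)
    out = np.matmul(w2[None], cols).reshape(bs, o, h, wd)

    def vjp_x(g):
        gf = g.reshape(bs, o, h * wd)
        dcols = np.matmul(w2.T[None], gf)  # (B, C*k*k, H*W)
        dcols = dcols.reshape(bs, c, k, k, h, wd)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + wd] += dcols[:, :, i, j]
        return dxp[:, :, pad : pad + h, pad : pad + wd]

    def vjp_w(g):
        gf = g.reshape(bs, o, h * wd)
        dw2 = np.einsum("bop,bkp->ok", gf, cols)
        return dw2.reshape(o, c, k, k)

    parents = [x, w]
    vjps = [vjp_x, vjp_w]
    if b is not None:
        out = out + b.value.reshape(1, o, 1, 1)
        parents.append(b)
        vjps.append(lambda g: g.sum(axis=(0, 2, 3)))
    return Tensor(out, parents=tuple(parents), vjps=tuple(vjps))


# -- modules ---------------------------------------------------------------


class Module:
    """Base class: tracks parameters through attribute discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params, seen):
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                if id(value) not in seen:
                    seen.add(id(value))
                    params.append(value)
            elif isinstance(value, Module):
                value._collect(params, seen)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item._collect(params, seen)
                    elif isinstance(item, Tensor) and item.requires_grad:
                        if id(item) not in seen:
                            seen.add(id(item))
                            params.append(item)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"state mismatch: {len(arrays)} arrays for {len(params)} parameters"
            )
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError(f"shape mismatch {p.value.shape} vs {a.shape}")
            p.value = np.asarray(a, dtype=np.float64)


def _param(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else 1.0 / np.sqrt(n_in)
        self.w = _param(rng, (n_in, n_out), scale) if not zero_init else Tensor(
            np.zeros((n_in, n_out)), requires_grad=True
        )
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.w = _param(rng, (c_out, c_in, k, k), 1.0 / np.sqrt(fan_in))
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)


class GroupNorm(Module):
    """Group normalisation over (B, C, H, W); composed from primitives so the
    gradient follows from the chain rule automatically."""

    def __init__(self, n_groups: int, n_channels: int, eps: float = 1e-5):
        if n_channels % n_groups != 0:
            raise ValueError("channels must divide into groups")
        self.n_groups = n_groups
        self.eps = eps
        self.gamma = Tensor(np.ones(n_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(n_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        g = self.n_groups
        xg = x.reshape(b, g, c // g * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=2, keepdims=True)
        norm = (xg - mu) / ((var + self.eps) ** 0.5)
        norm = norm.reshape(b, c, h, w)
        return norm * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)
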