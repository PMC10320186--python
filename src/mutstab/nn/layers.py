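"""Network building blocks: dense, convolutional and transformer-encoder
layers composed from the autograd primitives, plus an Adam optimiser."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerEncoderLayer",
    "Adam",
]


class Module:
    """Base class: parameter discovery by attribute walk (depth-first)."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"checkpoint has {len(arrays)} arrays, model expects {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Tensor(_glorot(rng, in_dim, out_dim, (in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Same-padded stride-1 convolution over (N, C_in, L)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        fan_in = in_channels * kernel
        self.weight = Tensor(
            _glorot(rng, fan_in, out_channels * kernel, (out_channels, in_channels, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias)


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gamma, self.beta)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over (N, L, D) with H heads."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads != 0:
            raise ValueError("dim must be divisible by heads")
        self.dim = dim
        self.heads = heads
        self.head_dim = dim // heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def _split(self, x: Tensor, n: int, L: int) -> Tensor:
        # (N, L, D) -> (N, H, L, d)
        return x.reshape(n, L, self.heads, self.head_dim).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        n, L, _ = x.shape
        q = self._split(self.wq(x), n, L)
        k = self._split(self.wk(x), n, L)
        v = self._split(self.wv(x), n, L)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
        attn = scores.softmax(axis=-1)
        ctx = attn @ v  # (N, H, L, d)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(n, L, self.dim)
        return self.wo(ctx)


class TransformerEncoderLayer(Module):
    """Pre-LN transformer encoder block: MHSA + position-wise feed-forward,
    each wrapped in residual connections."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator, ff_mult: int = 2):
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_mult * dim, rng)
        self.ff2 = Linear(ff_mult * dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        x = x + self.ff2(self.ff1(self.norm2(x)).relu())
        return x


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
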