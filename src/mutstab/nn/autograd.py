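"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operations the stability-prediction network needs:
broadcasting arithmetic, (batched) matmul, 1-D convolution, softmax,
layer normalisation, and the overflow-safe log-cosh used by the training
loss. Gradients are accumulated on a tape of ``Tensor`` nodes and released
by a topological backward sweep.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "concat", "logcosh"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_children", "_backward")

    def __init__(self, data, requires_grad: bool = False, _children=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._children = _children
        self._backward = _backward

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    # -- graph construction ------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, children, backward) -> "Tensor":
        req = any(c.requires_grad for c in children)
        return Tensor(data, req, children if req else (), backward if req else None)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return self._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities ---------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def abs(self):
        sign = np.sign(self.data)  # subgradient 0 at the kink

        def backward(g):
            if self.requires_grad:
                self._accum(g * sign)

        return self._make(np.abs(self.data), (self,), backward)

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        old = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        return self._make(self.data.transpose(*axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            if self.requires_grad:
                buf = np.zeros_like(self.data)
                np.add.at(buf, idx, g)
                self._accum(buf)

        return self._make(self.data[idx], (self,), backward)

    # -- fused primitives --------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (g - dot))

        return self._make(out_data, (self,), backward)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalise over the last axis: gamma * (x - mu)/sigma + beta."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        std = np.sqrt(var + eps)
        xhat = (x - mu) / std
        out_data = gamma.data * xhat + beta.data
        d = x.shape[-1]

        def backward(g):
            if gamma.requires_grad:
                gamma._accum(_unbroadcast(g * xhat, gamma.shape))
            if beta.requires_grad:
                beta._accum(_unbroadcast(g, beta.shape))
            if self.requires_grad:
                dxhat = g * gamma.data
                # standard layer-norm backward, fused
                dx = (
                    dxhat
                    - dxhat.mean(axis=-1, keepdims=True)
                    - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
                ) / std
                self._accum(dx)

        return self._make(out_data, (self, gamma, beta), backward)

    def conv1d(self, weight: "Tensor", bias: "Tensor"):
        """Same-padded stride-1 1-D convolution.

        self: (N, C_in, L); weight: (C_out, C_in, K) with odd K; bias: (C_out,).
        """
        x, w = self.data, weight.data
        n, cin, L = x.shape
        cout, _, k = w.shape
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        out_data = np.empty((n, cout, L))
        out_data[:] = bias.data[None, :, None]
        for j in range(k):
            out_data += np.einsum("oi,nil->nol", w[:, :, j], xp[:, :, j : j + L])

        def backward(g):
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2)))
            if weight.requires_grad:
                gw = np.empty_like(w)
                for j in range(k):
                    gw[:, :, j] = np.einsum("nol,nil->oi", g, xp[:, :, j : j + L])
                weight._accum(gw)
            if self.requires_grad:
                gxp = np.zeros_like(xp)
                for j in range(k):
                    gxp[:, :, j : j + L] += np.einsum("oi,nol->nil", w[:, :, j], g)
                self._accum(gxp[:, :, pad : pad + L])

        return self._make(out_data, (self, weight, bias), backward)

    def logcosh(self):
        """ln(cosh(x)), computed as |x| + log1p(exp(-2|x|)) - ln 2 (no overflow)."""
        ax = np.abs(self.data)
        out_data = ax + np.log1p(np.exp(-2.0 * ax)) - np.log(2.0)
        grad_local = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * grad_local)

        return self._make(out_data, (self,), backward)

    # -- backward sweep ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for child in node._children:
                if id(child) not in seen:
                    stack.append((child, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    req = any(t.requires_grad for t in tensors)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out = Tensor(out_data, req, tuple(tensors) if req else (), backward if req else None)
    return out


def logcosh(x: Tensor) -> Tensor:
    return x.logcosh()
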