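"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the package's 1D-convolutional and GRU
autoencoders: broadcast-aware elementwise ops, matmul, a strided conv1d with
an explicit col2im backward, nearest-neighbour upsampling, and an Adam
optimiser.  Gradient correctness is property-tested against central finite
differences.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- operators ------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            _accum(self, _unbroadcast(g, self.data.shape))
            _accum(other, _unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            _accum(self, -g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            _accum(self, _unbroadcast(g * other.data, self.data.shape))
            _accum(other, _unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        def bw(g):
            _accum(self, g @ other.data.T)
            _accum(other, self.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bw)

    # -- elementwise nonlinearities --------------------------------------
    def tanh(self):
        out = np.tanh(self.data)

        def bw(g):
            _accum(self, g * (1 - out**2))

        return Tensor(out, parents=(self,), backward=bw)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bw(g):
            _accum(self, g * out * (1 - out))

        return Tensor(out, parents=(self,), backward=bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            _accum(self, g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bw)

    # -- reductions / shape ----------------------------------------------
    def sum(self):
        def bw(g):
            _accum(self, np.full_like(self.data, float(g)))

        return Tensor(self.data.sum(), parents=(self,), backward=bw)

    def mean(self):
        return self.sum() / self.data.size

    def reshape(self, *shape):
        def bw(g):
            _accum(self, g.reshape(self.data.shape))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bw)

    def square(self):
        return self * self


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad and t.grad is not None:
        t.grad += g


def parameter(shape, rng: np.random.Generator, scale: float | None = None) -> Tensor:
    """Glorot-style initialised trainable tensor."""
    if scale is None:
        fan = np.prod(shape[:-1]) if len(shape) > 1 else shape[0]
        scale = 1.0 / np.sqrt(max(1, fan))
    return Tensor(rng.uniform(-scale, scale, shape), requires_grad=True)


def zeros(shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


# ---------------------------------------------------------------------------
def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """1D convolution: x (B, Cin, L), w (Cout, Cin, K), b (Cout,)."""
    B, Cin, L = x.data.shape
    Cout, _, K = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    Lout = (L + 2 * pad - K) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)[
        :, :, ::stride, :
    ]  # (B, Cin, Lout, K)
    out = np.einsum("bclk,ock->bol", windows, w.data) + b.data[None, :, None]

    def bw(g):  # g: (B, Cout, Lout)
        _accum(w, np.einsum("bol,bclk->ock", g, windows))
        _accum(b, g.sum(axis=(0, 2)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for k in range(K):
                # positions k, k+stride, ... receive w[:, :, k]
                dxp[:, :, k : k + Lout * stride : stride] += np.einsum(
                    "bol,oc->bcl", g, w.data[:, :, k]
                )
            _accum(x, dxp[:, :, pad : pad + L] if pad else dxp)

    return Tensor(out, parents=(x, w, b), backward=bw)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling along the last axis of (B, C, L)."""

    def bw(g):
        _accum(x, g.reshape(*x.data.shape, 2).sum(axis=-1))

    return Tensor(np.repeat(x.data, 2, axis=-1), parents=(x,), backward=bw)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m[:] = self.b1 * m + (1 - self.b1) * p.grad
            v[:] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
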