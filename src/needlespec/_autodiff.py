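"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the spectral-reconstruction network needs:
2-D convolution (odd kernels, "same" padding, implemented as a sum of
spatially shifted 1×1 products), ReLU/sigmoid/exp, elementwise arithmetic
with broadcasting, 2× average-pool down/nearest up-sampling, global average
pooling, channel-wise mean/max, concatenation, and reductions.  Tensors are
NCHW.  Gradients flow through a taped graph released after ``backward``.

This is deliberately small and CPU-oriented: the desk-scale networks in
this package have tens of thousands of parameters, for which NumPy matmuls
are entirely adequate.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(self, data, prev=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._backward = None
        self._prev = prev
        self.requires_grad = requires_grad or any(p.requires_grad for p in prev)

    @property
    def shape(self):
        return self.data.shape

    # -- graph bookkeeping ------------------------------------------------

    def _accum(self, grad):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.requires_grad:
                t._backward()
        # release the tape
        for t in topo:
            t._backward = None
            t._prev = ()

    # -- elementwise arithmetic -------------------------------------------

    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, (self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.shape)
                )

        out._backward = bw
        return out

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, (self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s))

        out._backward = bw
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, (self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * e)

        out._backward = bw
        return out

    def sqrt(self):
        s = np.sqrt(self.data)
        out = Tensor(s, (self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * 0.5 / np.maximum(s, 1e-300))

        out._backward = bw
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), (self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * np.sign(self.data))

        out._backward = bw
        return out

    # -- reductions --------------------------------------------------------

    def mean(self):
        out = Tensor(self.data.mean(), (self,))

        def bw():
            if self.requires_grad:
                self._accum(np.full_like(self.data, out.grad / self.data.size))

        out._backward = bw
        return out

    def mean_channels(self):
        """Mean over the channel axis, keepdims (N,1,H,W)."""
        out = Tensor(self.data.mean(axis=1, keepdims=True), (self,))

        def bw():
            if self.requires_grad:
                self._accum(
                    np.broadcast_to(out.grad / self.shape[1], self.shape).copy()
                )

        out._backward = bw
        return out

    def max_channels(self):
        """Max over the channel axis, keepdims; gradient to the argmax."""
        m = self.data.max(axis=1, keepdims=True)
        out = Tensor(m, (self,))

        def bw():
            if self.requires_grad:
                mask = self.data == m
                # split ties evenly
                self._accum(out.grad * mask / mask.sum(axis=1, keepdims=True))

        out._backward = bw
        return out

    def global_avg_pool(self):
        """Mean over spatial dims, keepdims (N,C,1,1)."""
        out = Tensor(self.data.mean(axis=(2, 3), keepdims=True), (self,))

        def bw():
            if self.requires_grad:
                n = self.shape[2] * self.shape[3]
                self._accum(np.broadcast_to(out.grad / n, self.shape).copy())

        out._backward = bw
        return out

    # -- resampling --------------------------------------------------------

    def avg_pool2(self):
        n, c, h, w = self.shape
        if h % 2 or w % 2:
            raise ValueError("avg_pool2 needs even spatial dims")
        y = self.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
        out = Tensor(y, (self,))

        def bw():
            if self.requires_grad:
                g = np.repeat(np.repeat(out.grad, 2, axis=2), 2, axis=3) / 4.0
                self._accum(g)

        out._backward = bw
        return out

    def upsample2(self):
        """Nearest-neighbour 2× upsampling."""
        y = np.repeat(np.repeat(self.data, 2, axis=2), 2, axis=3)
        out = Tensor(y, (self,))

        def bw():
            if self.requires_grad:
                n, c, h, w = out.shape
                g = out.grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
                self._accum(g)

        out._backward = bw
        return out

    # -- structural --------------------------------------------------------

    @staticmethod
    def concat(tensors, axis=1):
        data = np.concatenate([t.data for t in tensors], axis=axis)
        out = Tensor(data, tuple(tensors))
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw():
            pieces = np.split(out.grad, splits, axis=axis)
            for t, g in zip(tensors, pieces):
                if t.requires_grad:
                    t._accum(g)

        out._backward = bw
        return out

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None):
        """Same-padded 2-D convolution; ``weight`` is (O, C, k, k), k odd."""
        x, w = self.data, weight.data
        n, c, h, wd = x.shape
        o, c2, k, k2 = w.shape
        if c != c2 or k != k2 or k % 2 == 0:
            raise ValueError("weight must be (O, C, k, k) with odd k matching input")
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        y = np.zeros((n, o, h, wd))
        for di in range(k):
            for dj in range(k):
                patch = xp[:, :, di : di + h, dj : dj + wd]
                y += np.einsum("oc,nchw->nohw", w[:, :, di, dj], patch, optimize=True)
        if bias is not None:
            y += bias.data.reshape(1, o, 1, 1)
        prev = (self, weight) if bias is None else (self, weight, bias)
        out = Tensor(y, prev)

        def bw():
            gy = out.grad
            if weight.requires_grad:
                gw = np.empty_like(w)
                for di in range(k):
                    for dj in range(k):
                        patch = xp[:, :, di : di + h, dj : dj + wd]
                        gw[:, :, di, dj] = np.einsum(
                            "nohw,nchw->oc", gy, patch, optimize=True
                        )
                weight._accum(gw)
            if bias is not None and bias.requires_grad:
                bias._accum(gy.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gxp = np.zeros_like(xp)
                for di in range(k):
                    for dj in range(k):
                        gxp[:, :, di : di + h, dj : dj + wd] += np.einsum(
                            "oc,nohw->nchw", w[:, :, di, dj], gy, optimize=True
                        )
                self._accum(gxp[:, :, p : p + h, p : p + wd])

        out._backward = bw
        return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
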