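"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the tracking networks need: broadcasted
arithmetic, matmul, the usual pointwise nonlinearities, reductions, reshape /
concatenate / slicing, 2-D convolution (via im2col), and sampling through a
constant weight matrix (used for bilinear ROI pooling).  Gradients are
accumulated by a topological backward sweep from a scalar loss.

This is an internal engine: the public model API lives in
:mod:`ustrack.nets`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "conv2d", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the dimensions that were broadcast to reach its shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        g = np.asarray(g, dtype=np.float64)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad = self.grad + g

    def backward(self) -> None:
        """Backpropagate from this scalar tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                if other.data.ndim == 1 and self.data.ndim == 2:
                    self._accum(np.outer(g, other.data))
                elif self.data.ndim == 1:
                    self._accum(g @ other.data.T if other.data.ndim == 2 else g * other.data)
                else:
                    self._accum(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                if self.data.ndim == 1 and other.data.ndim == 2:
                    other._accum(np.outer(self.data, g))
                elif other.data.ndim == 1:
                    other._accum(self.data.T @ g if self.data.ndim == 2 else self.data * g)
                else:
                    other._accum(self.data.swapaxes(-1, -2) @ g)

        out._backward = bw
        return out

    # -- pointwise nonlinearities --------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (1.0 - out.data**2))
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * out.data * (1.0 - out.data))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (self.data > 0))
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * 0.5 / out.data)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * np.sign(self.data))
        return out

    def maximum0(self):
        """Elementwise max(x, 0) — alias of relu for hinge terms."""
        return self.relu()

    def clamp(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))
        mask = (self.data > lo) & (self.data < hi)
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    def arccos(self):
        # input is clamped by callers away from +-1 when gradients matter
        out = Tensor(np.arccos(self.data), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            -g / np.sqrt(np.maximum(1.0 - self.data**2, 1e-12))
        )
        return out

    def cos(self):
        out = Tensor(np.cos(self.data), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g * np.sin(self.data))
        return out

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            np.asarray(g).reshape(self.data.shape)
        )
        return out

    def flatten(self):
        return self.reshape(-1)

    def transpose(self, *axes):
        ax = axes if axes else None
        out = Tensor(self.data.transpose(ax), _parents=(self,))
        inv = np.argsort(ax) if ax else None
        out._backward = lambda g: self.requires_grad and self._accum(np.asarray(g).transpose(inv))
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out

    def norm(self):
        """Euclidean norm of the flattened tensor (scalar Tensor)."""
        return (self * self).sum().sqrt()

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _parents=tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out._backward = bw
    return out


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> tuple[np.ndarray, int, int]:
    """(C, H, W) -> (C*kh*kw, oh*ow) patch matrix."""
    c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    s0, s1, s2 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(c, oh, ow, kh, kw),
        strides=(s0, s1 * stride, s2 * stride, s1, s2),
        writeable=False,
    )
    cols = windows.transpose(0, 3, 4, 1, 2).reshape(c * kh * kw, oh * ow)
    return np.ascontiguousarray(cols), oh, ow


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation): x (C_in,H,W) -> (C_out,OH,OW)."""
    xd = x.data
    if pad:
        xd = np.pad(xd, ((0, 0), (pad, pad), (pad, pad)))
    c_out, c_in, kh, kw = weight.data.shape
    cols, oh, ow = _im2col(xd, kh, kw, stride)
    wmat = weight.data.reshape(c_out, -1)
    out_data = (wmat @ cols + bias.data[:, None]).reshape(c_out, oh, ow)
    out = Tensor(out_data, _parents=(x, weight, bias))

    def bw(g):
        gmat = g.reshape(c_out, -1)
        if bias.requires_grad:
            bias._accum(gmat.sum(axis=1))
        if weight.requires_grad:
            weight._accum((gmat @ cols.T).reshape(weight.data.shape))
        if x.requires_grad:
            dcols = wmat.T @ gmat  # (C_in*kh*kw, oh*ow)
            dx = np.zeros_like(xd)
            dcols_r = dcols.reshape(c_in, kh, kw, oh, ow)
            for i in range(kh):
                for j in range(kw):
                    dx[:, i : i + oh * stride : stride, j : j + ow * stride : stride] += dcols_r[
                        :, i, j
                    ]
            if pad:
                dx = dx[:, pad:-pad, pad:-pad]
            x._accum(dx)

    out._backward = bw
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

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

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
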