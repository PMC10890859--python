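"""Minimal reverse-mode automatic differentiation on numpy arrays.

A tape-based scalar-loss autodiff engine carrying exactly the operations the
reconstruction networks need: broadcasting arithmetic, batched matmul, 2D
convolution (stride 1), pooling/reductions, softmax, layer normalisation and
elementwise nonlinearities. Gradients are accumulated by topological sweep
from the loss tensor.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to the original operand shape."""
    if grad.shape == shape:
        return grad
    ndim_diff = grad.ndim - len(shape)
    if ndim_diff > 0:
        grad = grad.sum(axis=tuple(range(ndim_diff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward_fn=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(
            requires_grad or any(p.requires_grad for p in _parents)
        )
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward_fn = _backward_fn

    # ---- graph mechanics -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> np.ndarray:
        return self.data

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward_fn is None or node.grad is None:
                continue
            grads = node._backward_fn(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(parent.data.dtype, copy=True)
                else:
                    parent.grad += g

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor(out_data, _parents=(self, other), _backward_fn=bw)

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _backward_fn=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor(out_data, _parents=(self, other), _backward_fn=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor(out_data, _parents=(self, other), _backward_fn=bw)

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def bw(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return Tensor(out_data, _parents=(self,), _backward_fn=bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def bw(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor(out_data, _parents=(self, other), _backward_fn=bw)

    # ---- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape
        out = Tensor(
            self.data.reshape(*shape),
            _parents=(self,),
            _backward_fn=lambda g: (g.reshape(orig),),
        )
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(*axes),
            _parents=(self,),
            _backward_fn=lambda g: (g.transpose(*inv),),
        )

    def roll(self, shift, axis):
        neg = tuple(-s for s in shift) if isinstance(shift, tuple) else -shift
        return Tensor(
            np.roll(self.data, shift, axis=axis),
            _parents=(self,),
            _backward_fn=lambda g: (np.roll(g, neg, axis=axis),),
        )

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        return Tensor(out_data, _parents=(self,), _backward_fn=bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- nonlinearities --------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor(
            self.data * mask, _parents=(self,), _backward_fn=lambda g: (g * mask,)
        )

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(
            out_data,
            _parents=(self,),
            _backward_fn=lambda g: (g * out_data * (1.0 - out_data),),
        )

    def gelu(self):
        """tanh-approximation GELU."""
        c = np.sqrt(2.0 / np.pi)
        x = self.data
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def bw(g):
            dinner = c * (1.0 + 3 * 0.044715 * x**2)
            d = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner
            return (g * d,)

        return Tensor(out_data, _parents=(self,), _backward_fn=bw)

    def abs(self):
        s = np.sign(self.data)
        return Tensor(
            np.abs(self.data), _parents=(self,), _backward_fn=lambda g: (g * s,)
        )

    def softmax(self, axis=-1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return (out_data * (g - dot),)

        return Tensor(out_data, _parents=(self,), _backward_fn=bw)

    def layer_norm(self, eps: float = 1e-5):
        """Normalise over the last axis to zero mean, unit variance."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        out_data = xc * inv
        n = self.shape[-1]

        def bw(g):
            gm = g.mean(axis=-1, keepdims=True)
            gxm = (g * out_data).mean(axis=-1, keepdims=True)
            return (inv * (g - gm - out_data * gxm),)

        return Tensor(out_data, _parents=(self,), _backward_fn=bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int | None = None) -> Tensor:
    """'Same' 2D correlation, stride 1: x (N,C,H,W), w (F,C,kh,kw), b (F,).

    Implemented with a sliding-window view and einsum; the backward pass for
    the input is the transposed convolution expressed the same way.
    """
    n, c, h, wd = x.shape
    f, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("kernels must have odd spatial size")
    if padding is None:
        padding = kh // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    out_data = np.einsum("nchwij,fcij->nfhw", windows, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def bw(g):
        gw = np.einsum("nfhw,nchwij->fcij", g, windows, optimize=True)
        # dx: correlate upstream grad with the kernel flipped in space,
        # channels and filters swapped.
        gp = np.pad(g, ((0, 0), (0, 0), (kh - 1 - padding,) * 2, (kw - 1 - padding,) * 2))
        gwin = np.lib.stride_tricks.sliding_window_view(gp, (kh, kw), axis=(2, 3))
        w_flip = w.data[:, :, ::-1, ::-1]
        gx = np.einsum("nfhwij,fcij->nchw", gwin, w_flip, optimize=True)
        gb = g.sum(axis=(0, 2, 3)) if b is not None else None
        return gx, gw, gb

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, _parents=parents, _backward_fn=bw)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.stack(datas, axis=axis)

    def bw(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

    return Tensor(out_data, _parents=tuple(tensors), _backward_fn=bw)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(target)
    return (diff * diff).mean()


def l1_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    return (pred - Tensor(target)).abs().mean()
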