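"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package's differentiable components (the learnable strong augmenter,
the adaptive gates, the dual-branch detector, and the test-time updates)
are small convolutional networks, so a compact tape-based engine is all
that is needed.  A :class:`Tensor` wraps a float64 ``numpy`` array and
records the operations applied to it; :meth:`Tensor.backward` walks the
tape in reverse topological order and accumulates gradients.

Only the operations the model zoo actually uses are implemented:
elementwise arithmetic with broadcasting, matmul, 2-D convolution via
im2col, sigmoid / tanh / GeLU / leaky-ReLU, log / exp, reductions,
reshape / transpose / indexing / stack / concatenate, nearest-neighbour
upsampling and value clipping (straight-through inside the range).
"""

from __future__ import annotations

import contextlib
import math

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables tape recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        return x.data
    return np.asarray(x, dtype=np.float64)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd -------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=np.float64)

        # topological order over the tape
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                if node.requires_grad:  # leaf
                    node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data
        return Tensor._make(
            out_data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data
        return Tensor._make(
            out_data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data
        return Tensor._make(
            out_data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data**e
        return Tensor._make(
            out_data, (self,), lambda g: (g * e * self.data ** (e - 1.0),)
        )

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 2:
                ga, gb = g @ b.T, np.outer(a, g)
            elif a.ndim == 2 and b.ndim == 1:
                ga, gb = np.outer(g, b), a.T @ g
            elif a.ndim == 1 and b.ndim == 1:
                ga, gb = g * b, g * a
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
                ga = _unbroadcast(ga, a.shape)
                gb = _unbroadcast(gb, b.shape)
            return ga, gb

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(s, (self,), lambda g: (g * s * (1.0 - s),))

    def softplus(self):
        x = self.data
        out_data = np.logaddexp(0.0, x)
        s = 1.0 / (1.0 + np.exp(-x))
        return Tensor._make(out_data, (self,), lambda g: (g * s,))

    def tanh(self):
        t = np.tanh(self.data)
        return Tensor._make(t, (self,), lambda g: (g * (1.0 - t * t),))

    def gelu(self):
        """Exact GeLU: x * Phi(x) with the Gaussian CDF Phi."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        out_data = x * phi
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
        return Tensor._make(out_data, (self,), lambda g: (g * (phi + x * pdf),))

    def leaky_relu(self, slope: float = 0.1):
        x = self.data
        out_data = np.where(x > 0, x, slope * x)
        return Tensor._make(
            out_data, (self,), lambda g: (g * np.where(x > 0, 1.0, slope),)
        )

    def clip(self, lo: float, hi: float):
        """Clip values; gradient passes through where not clipped."""
        x = self.data
        out_data = np.clip(x, lo, hi)
        inside = (x >= lo) & (x <= hi)
        return Tensor._make(out_data, (self,), lambda g: (g * inside,))

    def maximum(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = np.maximum(self.data, other.data)
        pick = self.data >= other.data  # ties route to the first argument
        return Tensor._make(
            out_data,
            (self, other),
            lambda g: (
                _unbroadcast(g * pick, self.shape),
                _unbroadcast(g * ~pick, other.shape),
            ),
        )

    def minimum(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = np.minimum(self.data, other.data)
        pick = self.data <= other.data
        return Tensor._make(
            out_data,
            (self, other),
            lambda g: (
                _unbroadcast(g * pick, self.shape),
                _unbroadcast(g * ~pick, other.shape),
            ),
        )

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.ndim for a in axes)
                for a in sorted(axes):
                    g2 = np.expand_dims(g2, a)
            return (np.broadcast_to(g2, self.shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a % self.ndim] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(out_data, (self,), backward)

    def repeat_nearest(self, factor: int):
        """Nearest-neighbour upsample of the trailing two axes by ``factor``."""
        f = int(factor)
        out_data = self.data.repeat(f, axis=-2).repeat(f, axis=-1)
        h, w = self.shape[-2], self.shape[-1]

        def backward(g):
            shp = g.shape[:-2] + (h, f, w, f)
            return (g.reshape(shp).sum(axis=(-3, -1)),)

        return Tensor._make(out_data, (self,), backward)

    # -- convolution ----------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor" = None, stride: int = 1,
               padding: int = 0):
        """2-D convolution (cross-correlation): input (N,C,H,W), weight (O,C,kh,kw)."""
        x, w = self.data, weight.data
        n, c, h, wid = x.shape
        o, c2, kh, kw = w.shape
        if c != c2:
            raise ValueError(f"channel mismatch: input {c} vs weight {c2}")
        s, p = int(stride), int(padding)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        oh = (h + 2 * p - kh) // s + 1
        ow = (wid + 2 * p - kw) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::s, ::s]                       # (N,C,oh,ow,kh,kw)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
        wmat = w.reshape(o, c * kh * kw)
        out = cols @ wmat.T                             # (N*oh*ow, O)
        out = out.reshape(n, oh, ow, o).transpose(0, 3, 1, 2)
        if bias is not None:
            out = out + bias.data.reshape(1, o, 1, 1)

        def backward(g):
            gmat = g.transpose(0, 2, 3, 1).reshape(n * oh * ow, o)
            gw = (gmat.T @ cols).reshape(w.shape)
            gcols = gmat @ wmat                         # (N*oh*ow, C*kh*kw)
            gcols = gcols.reshape(n, oh, ow, c, kh, kw)
            gxp = np.zeros((n, c, h + 2 * p, wid + 2 * p))
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += (
                        gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            gx = gxp[:, :, p:p + h, p:p + wid] if p else gxp
            gb = g.sum(axis=(0, 2, 3)) if bias is not None else None
            return (gx, gw, gb) if bias is not None else (gx, gw)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out, parents, backward)


# -- free functions ------------------------------------------------------------

def stack(tensors: list, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.stack(datas, axis=axis)

    def backward(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

    return Tensor._make(out_data, tuple(tensors), backward)


def concatenate(tensors: list, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        return tuple(
            np.take(g, range(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(tensors))
        )

    return Tensor._make(out_data, tuple(tensors), backward)
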