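"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine in the spirit of micrograd, generalised to
n-dimensional arrays with broadcasting.  It exists so the fusion network can
be trained on a plain CPU stack: every differentiable building block the
model needs (dense/conv layers, attention, layer norm, the contrastive and
task losses) is expressed in the primitives below.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which topologically sorts the recorded graph.  All primitives implement the
vector-Jacobian product directly; correctness is pinned by finite-difference
checks in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf as _erf

__all__ = ["Tensor", "concat", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
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
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- bookkeeping -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[["Tensor"], None] | None) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        a, b = self, other

        def backward(out):
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(out.grad, b.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(out):
            if a.requires_grad:
                a._accum(-out.grad)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        a, b = self, other

        def backward(out):
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(out.grad * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        a = self
        p = float(p)

        def backward(out):
            if a.requires_grad:
                a._accum(out.grad * p * a.data ** (p - 1.0))

        return Tensor._make(a.data ** p, (a,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        a, b = self, other

        def backward(out):
            if a.requires_grad:
                a._accum(out.grad @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ out.grad)

        return Tensor._make(a.data @ b.data, (a, b), backward)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def backward(out):
            if a.requires_grad:
                a._accum(out.grad.reshape(old))

        return Tensor._make(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def backward(out):
            if a.requires_grad:
                a._accum(out.grad.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        a = self

        def backward(out):
            if a.requires_grad:
                g = np.zeros_like(a.data)
                np.add.at(g, idx, out.grad)
                a._accum(g)

        return Tensor._make(a.data[idx], (a,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(out):
            if a.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.max(axis=axis, keepdims=keepdims)

        def backward(out):
            if a.requires_grad:
                expanded = out_data if keepdims or axis is None else np.expand_dims(
                    out_data, axis)
                mask = (a.data == expanded).astype(np.float64)
                mask /= mask.sum(axis=axis, keepdims=True)  # split ties evenly
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(mask * g)

        return Tensor._make(out_data, (a,), backward)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(out):
            if a.requires_grad:
                a._accum(out.grad * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(out):
            if a.requires_grad:
                a._accum(out.grad / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def relu(self):
        a = self

        def backward(out):
            if a.requires_grad:
                a._accum(out.grad * (a.data > 0))

        return Tensor._make(np.maximum(a.data, 0.0), (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(out):
            if a.requires_grad:
                a._accum(out.grad * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(out):
            if a.requires_grad:
                a._accum(out.grad * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (a,), backward)

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        a = self
        cdf = 0.5 * (1.0 + _erf(a.data / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * a.data ** 2) / np.sqrt(2.0 * np.pi)

        def backward(out):
            if a.requires_grad:
                a._accum(out.grad * (cdf + a.data * pdf))

        return Tensor._make(a.data * cdf, (a,), backward)

    # -- convolution -------------------------------------------------------
    def conv2d(self, weight: "Tensor", stride: int = 1, padding: int = 0):
        """2-D cross-correlation: self (B,C,H,W) with weight (O,C,kh,kw)."""
        a, w = self, weight
        B, C, H, W = a.shape
        O, Cw, kh, kw = w.shape
        if C != Cw:
            raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
        s, p = int(stride), int(padding)
        xp = np.pad(a.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else a.data
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (B, C, Ho, Wo, kh, kw)
        out_data = np.einsum("bchwij,ocij->bohw", win, w.data, optimize=True)
        Ho, Wo = out_data.shape[2:]

        def backward(out):
            g = out.grad  # (B, O, Ho, Wo)
            if w.requires_grad:
                w._accum(np.einsum("bchwij,bohw->ocij", win, g, optimize=True))
            if a.requires_grad:
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i:i + Ho * s:s, j:j + Wo * s:s] += np.einsum(
                            "bohw,oc->bchw", g, w.data[:, :, i, j], optimize=True)
                a._accum(gxp[:, :, p:p + H, p:p + W] if p else gxp)

        return Tensor._make(out_data, (a, w), backward)

    # -- autodiff ----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
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
            for parent in node._parents:
                if parent.requires_grad and id(parent) not in seen:
                    stack.append((parent, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node)
                node._backward = None  # free the closure
            if node is not self and node._parents:
                node.grad = None  # intermediate grads are not retained
            node._parents = ()


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [(_as_tensor(t)) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(out):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in ts], axis=axis), ts, backward)
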