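"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ``ndarray`` and
records, for every differentiable operation, a closure that propagates the
upstream gradient to its parents.  ``Tensor.backward()`` runs a topological
sort of the recorded graph and accumulates gradients.  Only the operations
the segmentation network needs are implemented (elementwise arithmetic,
exp/log, ReLU, sigmoid, reductions, reshape, concatenate, and the 2-D
convolution family in :mod:`rdaunet.nn.conv_ops`).

Gradient correctness is validated against central finite differences in the
test-suite; the engine is single-threaded and fully deterministic.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes that were added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = backward
        self._parents = tuple(parents)

    # ------------------------------------------------------------------ util
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or not g.flags.owndata else g
        else:
            self.grad = self.grad + g

    # -------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------ arithmetic
    def _wrap(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        arr = np.asarray(other)
        if arr.ndim == 0:  # scalars follow this tensor's dtype (no promotion)
            arr = arr.astype(self.data.dtype)
        return Tensor(arr)

    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data + other.data, out_req, (self, other))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd if out_req else None
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data * other.data, out_req, (self, other))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd if out_req else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._wrap(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data / other.data, out_req, (self, other))

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bwd if out_req else None
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return self._wrap(other) / self

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data**p, self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    # ----------------------------------------------------------- elementwise
    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g * val)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def sigmoid(self) -> "Tensor":
        from scipy.special import expit  # numerically stable logistic

        val = expit(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g * val * (1.0 - val))
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes only where unclamped."""
        mask = (self.data > lo) & (self.data < hi)
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))
        if self.requires_grad:
            shape = self.data.shape

            def bwd(g: np.ndarray) -> None:
                if axis is None:
                    self._accumulate(np.broadcast_to(g, shape))
                    return
                gg = g
                if not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    for ax in sorted(a % len(shape) for a in axes):
                        gg = np.expand_dims(gg, ax)
                self._accumulate(np.broadcast_to(gg, shape))

            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out


def concatenate(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    """Differentiable concatenation along ``axis``."""
    ts = list(tensors)
    req = any(t.requires_grad for t in ts)
    out = Tensor(np.concatenate([t.data for t in ts], axis=axis), req, ts)
    if req:
        sizes = [t.data.shape[axis] for t in ts]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g: np.ndarray) -> None:
            for t, piece in zip(ts, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)

        out._backward = bwd
    return out
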