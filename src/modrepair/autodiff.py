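"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a numpy array and records the operations applied to
it on a tape (the ``_parents`` / ``_backward`` links).  Calling
:meth:`Tensor.backward` on a scalar output walks the tape in reverse
topological order and accumulates gradients into every tensor created with
``requires_grad=True``.

The op set is deliberately small: exactly what the convolutional encoders,
attention fusion, and self-supervised losses in this package need.  All
arithmetic supports numpy broadcasting; gradients of broadcast operands are
summed back to the operand's shape.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64 if np.asarray(x).dtype == np.float64 else np.float32))


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ basic
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _needs_tape(self, *others: "Tensor") -> bool:
        return self.requires_grad or self._parents or any(
            o.requires_grad or o._parents for o in others
        )

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out_data = self.data + other.data
        if not self._needs_tape(other):
            return Tensor(out_data)

        def backward(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        if not self._needs_tape():
            return Tensor(-self.data)
        return Tensor(-self.data, _parents=(self,), _backward=lambda g, out: (-g,))

    def __sub__(self, other) -> "Tensor":
        return self + (-_as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return _as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out_data = self.data * other.data
        if not self._needs_tape(other):
            return Tensor(out_data)
        a_data, b_data = self.data, other.data

        def backward(g, out):
            return (_unbroadcast(g * b_data, self.shape),
                    _unbroadcast(g * a_data, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = _as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, p: float) -> "Tensor":
        out_data = self.data ** p
        if not self._needs_tape():
            return Tensor(out_data)
        x = self.data

        def backward(g, out):
            return (g * p * x ** (p - 1.0),)

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def __matmul__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out_data = self.data @ other.data
        if not self._needs_tape(other):
            return Tensor(out_data)
        a, b = self.data, other.data

        def backward(g, out):
            return (g @ b.T, a.T @ g)

        return Tensor(out_data, _parents=(self, other), _backward=backward)

    # ------------------------------------------------------------ elementwise
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        if not self._needs_tape():
            return Tensor(out_data)

        def backward(g, out):
            return (g * out.data,)

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)
        if not self._needs_tape():
            return Tensor(out_data)
        x = self.data

        def backward(g, out):
            return (g / x,)

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)
        if not self._needs_tape():
            return Tensor(out_data)

        def backward(g, out):
            return (g * (1.0 - out.data ** 2),)

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def sigmoid(self) -> "Tensor":
        # numerically stable logistic
        x = self.data
        out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                            np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        if not self._needs_tape():
            return Tensor(out_data)

        def backward(g, out):
            return (g * out.data * (1.0 - out.data),)

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0)
        if not self._needs_tape():
            return Tensor(out_data)
        mask = self.data > 0

        def backward(g, out):
            return (g * mask,)

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def abs(self) -> "Tensor":
        out_data = np.abs(self.data)
        if not self._needs_tape():
            return Tensor(out_data)
        sign = np.sign(self.data)

        def backward(g, out):
            return (g * sign,)

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def clamp(self, lo: float, hi: float) -> "Tensor":
        """Clip to [lo, hi]; gradient is 1 strictly inside, 0 outside."""
        out_data = np.clip(self.data, lo, hi)
        if not self._needs_tape():
            return Tensor(out_data)
        mask = (self.data > lo) & (self.data < hi)

        def backward(g, out):
            return (g * mask,)

        return Tensor(out_data, _parents=(self,), _backward=backward)

    # -------------------------------------------------------------- reduction
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        if not self._needs_tape():
            return Tensor(out_data)
        shape = self.shape

        def backward(g, out):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % len(shape) for a in axes)
                gg = np.expand_dims(gg, axes)
            return (np.broadcast_to(gg, shape).copy(),)

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else (
            np.prod([self.shape[a % self.ndim]
                     for a in (axis if isinstance(axis, tuple) else (axis,))])
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        if not self._needs_tape():
            return Tensor(out_data)
        orig = self.shape

        def backward(g, out):
            return (g.reshape(orig),)

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        out_data = self.data.transpose(axes)
        if not self._needs_tape():
            return Tensor(out_data)
        inv = np.argsort(axes)

        def backward(g, out):
            return (g.transpose(inv),)

        return Tensor(out_data, _parents=(self,), _backward=backward)

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]
        if not self._needs_tape():
            return Tensor(out_data)
        shape = self.shape
        dtype = self.data.dtype

        def backward(g, out):
            gx = np.zeros(shape, dtype=dtype)
            np.add.at(gx, idx, g)
            return (gx,)

        return Tensor(out_data, _parents=(self,), _backward=backward)

    # ------------------------------------------------------------ convolution
    def conv1d_same(self, weight: "Tensor", bias: "Tensor | None" = None) -> "Tensor":
        """1-D convolution, stride 1, zero same-padding.

        self: (N, C_in, T); weight: (C_out, C_in, K) with odd K;
        bias: (C_out,).  Returns (N, C_out, T).
        """
        x, w = self.data, weight.data
        n, c_in, t = x.shape
        c_out, c_in_w, k = w.shape
        if c_in != c_in_w:
            raise ValueError(
                f"conv1d: input has {c_in} channels but weight expects {c_in_w}")
        if k % 2 != 1:
            raise ValueError("conv1d_same requires odd kernel size")
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # K batched matmuls over kernel offsets (avoids im2col copies)
        out_data = np.matmul(w[:, :, 0], xp[:, :, 0:t])
        for kk in range(1, k):
            out_data += np.matmul(w[:, :, kk], xp[:, :, kk:kk + t])
        if bias is not None:
            out_data += bias.data[None, :, None]

        parents = (self, weight) if bias is None else (self, weight, bias)
        if not self._needs_tape(*parents[1:]):
            return Tensor(out_data)

        def backward(g, out):
            # g: (N, C_out, T)
            gxp = np.zeros_like(xp)
            gw = np.empty_like(w)
            for kk in range(k):
                gxp[:, :, kk:kk + t] += np.matmul(w[:, :, kk].T, g)
                gw[:, :, kk] = np.tensordot(g, xp[:, :, kk:kk + t],
                                            axes=([0, 2], [0, 2]))
            gx = gxp[:, :, pad:pad + t] if pad else gxp
            if bias is None:
                return (gx, gw)
            return (gx, gw, g.sum(axis=(0, 2)))

        return Tensor(out_data, _parents=parents, _backward=backward)

    # --------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data, dtype=np.float64 if self.data.dtype == np.float64 else np.float32)
        # reverse topological order
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
                if id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            parent_grads = node._backward(g, node)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    def zero_grad(self) -> None:
        self.grad = None


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, axes: tuple[int, ...],
              eps: float = 1e-5,
              stats: tuple[np.ndarray, np.ndarray] | None = None,
              stats_are_batch: bool = True) -> Tensor:
    """Fused batch-normalization primitive.

    Normalizes ``x`` per channel over ``axes`` with mean/var ``stats``
    (both 1-D of length C; computed internally from the batch when
    ``None``).  ``stats_are_batch`` selects the backward formula: True
    means the statistics are functions of ``x`` (training mode), False
    means they are fixed constants (evaluation mode, running statistics).
    ``gamma``/``beta`` are 1-D of length C.
    """
    bshape = tuple(1 if a in axes else s for a, s in enumerate(x.shape))
    xd = x.data
    if stats is None:
        mu = xd.mean(axis=axes, keepdims=True)
        var = ((xd - mu) ** 2).mean(axis=axes, keepdims=True)
    else:
        mu = np.asarray(stats[0], dtype=xd.dtype).reshape(bshape)
        var = np.asarray(stats[1], dtype=xd.dtype).reshape(bshape)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu) * inv_std
    gb = gamma.data.reshape(bshape)
    bb = beta.data.reshape(bshape)
    out_data = gb * xhat + bb
    if not x._needs_tape(gamma, beta):
        return Tensor(out_data)

    def backward(g, out):
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        dxhat = g * gb
        if stats_are_batch:
            dx = inv_std * (dxhat
                            - dxhat.mean(axis=axes, keepdims=True)
                            - xhat * (dxhat * xhat).mean(axis=axes,
                                                         keepdims=True))
        else:
            dx = dxhat * inv_std
        return (dx, dgamma, dbeta)

    return Tensor(out_data, _parents=(x, gamma, beta), _backward=backward)


# ------------------------------------------------------------------- helpers
def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient support."""
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    if not any(t.requires_grad or t._parents for t in tensors):
        return Tensor(out_data)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g, out):
        return tuple(np.ascontiguousarray(p) for p in np.split(g, splits, axis=axis))

    return Tensor(out_data, _parents=tuple(tensors), _backward=backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Stack tensors along a new axis with gradient support."""
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)
    if not any(t.requires_grad or t._parents for t in tensors):
        return Tensor(out_data)

    def backward(g, out):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

    return Tensor(out_data, _parents=tuple(tensors), _backward=backward)
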