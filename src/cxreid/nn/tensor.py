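"""Reverse-mode automatic differentiation on numpy arrays.

A minimal tape-based autograd: each :class:`Tensor` wraps an ``ndarray`` and
remembers the operation that produced it. Calling :meth:`Tensor.backward` on a
scalar walks the tape in reverse topological order and accumulates gradients
into every tensor with ``requires_grad=True``. Only the operations needed by
the siamese verification/retrieval models are implemented (elementwise
arithmetic, batched matmul, conv-style unfold/fold, pooling, sigmoid/relu,
reductions, concatenation).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        if self.data.size != 1:
            raise ValueError("item() requires a single-element tensor")
        return float(self.data.reshape(()))

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- tape -----------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion limits
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
            node._backward = None
            node._parents = ()

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy() if isinstance(grad, np.ndarray) else np.asarray(grad)
        else:
            self.grad += grad

    # -- operators ------------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, exponent):
        return power(self, exponent)

    def sum(self, axis=None, keepdims=False):
        return tensor_sum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tensor_mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, axes):
        return transpose(self, axes)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data, parents, backward) -> Tensor:
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    if not req:
        return Tensor(data)
    return Tensor(data, requires_grad=True, parents=tuple(p for p in parents if p.requires_grad),
                  backward=backward)


# -- primitive operations -----------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(grad):
        if a.requires_grad:
            a._accumulate(_unbroadcast(grad, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(grad, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b) -> Tensor:
    a = _as_tensor(a)
    if not isinstance(b, Tensor):
        b_arr = np.asarray(b, dtype=a.data.dtype)
        out_data = a.data * b_arr

        def backward_scalar(grad):
            if a.requires_grad:
                a._accumulate(_unbroadcast(grad * b_arr, a.data.shape))

        return _make(out_data, (a,), backward_scalar)

    out_data = a.data * b.data

    def backward(grad):
        if a.requires_grad:
            a._accumulate(_unbroadcast(grad * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(grad * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def power(a: Tensor, exponent: float) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data ** exponent

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad * exponent * a.data ** (exponent - 1.0))

    return _make(out_data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward(grad):
        if a.requires_grad:
            ga = grad @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ grad
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), backward)


def relu(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad * mask)

    return _make(out_data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    # numerically stable logistic
    out_data = np.empty_like(a.data)
    pos = a.data >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ex = np.exp(a.data[~pos])
    out_data[~pos] = ex / (1.0 + ex)

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def exp(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad * out_data)

    return _make(out_data, (a,), backward)


def log(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    out_data = np.log(a.data)

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad / a.data)

    return _make(out_data, (a,), backward)


def sqrt(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    out_data = np.sqrt(a.data)

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad * 0.5 / out_data)

    return _make(out_data, (a,), backward)


def absolute(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    sign = np.sign(a.data)
    out_data = np.abs(a.data)

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad * sign)

    return _make(out_data, (a,), backward)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp with zero gradient outside [lo, hi]."""
    a = _as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad * mask)

    return _make(out_data, (a,), backward)


def maximum_const(a: Tensor, c: float) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > c
    out_data = np.where(mask, a.data, c)

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad * mask)

    return _make(out_data, (a,), backward)


def tensor_sum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(grad):
        if not a.requires_grad:
            return
        g = np.asarray(grad)
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(a_ % a.data.ndim for a_ in axes):
                g = np.expand_dims(g, ax)
        a._accumulate(np.broadcast_to(g, a.data.shape).astype(a.data.dtype, copy=False))

    return _make(out_data, (a,), backward)


def tensor_mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(tensor_sum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a: Tensor, shape) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad.transpose(inv))

    return _make(out_data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * grad.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(grad[tuple(idx)])

    return _make(out_data, tuple(ts), backward)


def take(a: Tensor, indices) -> Tensor:
    """Row gather along axis 0 (duplicates allowed; gradients accumulate)."""
    a = _as_tensor(a)
    idx = np.asarray(indices)
    out_data = a.data[idx]

    def backward(grad):
        if a.requires_grad:
            g = np.zeros_like(a.data)
            np.add.at(g, idx, grad)
            a._accumulate(g)

    return _make(out_data, (a,), backward)


def unfold(x: Tensor, kernel: int, stride: int = 1, pad: int = 0) -> Tensor:
    """im2col: (B, C, H, W) -> (B, C*k*k, Ho*Wo)."""
    x = _as_tensor(x)
    B, C, H, W = x.data.shape
    Ho = (H + 2 * pad - kernel) // stride + 1
    Wo = (W + 2 * pad - kernel) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    cols = np.empty((B, C, kernel, kernel, Ho, Wo), dtype=x.data.dtype)
    for ki in range(kernel):
        for kj in range(kernel):
            cols[:, :, ki, kj] = xp[:, :, ki:ki + stride * Ho:stride,
                                    kj:kj + stride * Wo:stride]
    out_data = cols.reshape(B, C * kernel * kernel, Ho * Wo)

    def backward(grad):
        if not x.requires_grad:
            return
        g = grad.reshape(B, C, kernel, kernel, Ho, Wo)
        gp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=grad.dtype)
        for ki in range(kernel):
            for kj in range(kernel):
                gp[:, :, ki:ki + stride * Ho:stride, kj:kj + stride * Wo:stride] \
                    += g[:, :, ki, kj]
        x._accumulate(gp[:, :, pad:pad + H, pad:pad + W] if pad else gp)

    return _make(out_data, (x,), backward)


def max_pool2d(x: Tensor, kernel: int = 2) -> Tensor:
    """Non-overlapping max pooling; spatial dims must divide by ``kernel``."""
    x = _as_tensor(x)
    B, C, H, W = x.data.shape
    if H % kernel or W % kernel:
        raise ValueError(f"spatial size ({H},{W}) not divisible by pool kernel {kernel}")
    Ho, Wo = H // kernel, W // kernel
    windows = x.data.reshape(B, C, Ho, kernel, Wo, kernel).transpose(0, 1, 2, 4, 3, 5)
    flat = windows.reshape(B, C, Ho, Wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(grad):
        if not x.requires_grad:
            return
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, arg[..., None], grad[..., None], axis=-1)
        g = gflat.reshape(B, C, Ho, Wo, kernel, kernel).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(g.reshape(B, C, H, W))

    return _make(out_data, (x,), backward)


def _adaptive_bounds(in_size: int, out_size: int):
    starts = (np.arange(out_size) * in_size) // out_size
    ends = -((-(np.arange(1, out_size + 1) * in_size)) // out_size)  # ceil
    return starts, ends


def adaptive_avg_pool2d(x: Tensor, out_hw: int) -> Tensor:
    x = _as_tensor(x)
    B, C, H, W = x.data.shape
    hs, he = _adaptive_bounds(H, out_hw)
    ws, we = _adaptive_bounds(W, out_hw)
    out_data = np.empty((B, C, out_hw, out_hw), dtype=x.data.dtype)
    for i in range(out_hw):
        for j in range(out_hw):
            out_data[:, :, i, j] = x.data[:, :, hs[i]:he[i], ws[j]:we[j]].mean(axis=(2, 3))

    def backward(grad):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        for i in range(out_hw):
            for j in range(out_hw):
                area = (he[i] - hs[i]) * (we[j] - ws[j])
                gx[:, :, hs[i]:he[i], ws[j]:we[j]] += grad[:, :, i:i + 1, j:j + 1] / area
        x._accumulate(gx)

    return _make(out_data, (x,), backward)


def adaptive_max_pool2d(x: Tensor, out_hw: int) -> Tensor:
    x = _as_tensor(x)
    B, C, H, W = x.data.shape
    hs, he = _adaptive_bounds(H, out_hw)
    ws, we = _adaptive_bounds(W, out_hw)
    out_data = np.empty((B, C, out_hw, out_hw), dtype=x.data.dtype)
    args = []
    for i in range(out_hw):
        row = []
        for j in range(out_hw):
            win = x.data[:, :, hs[i]:he[i], ws[j]:we[j]].reshape(B, C, -1)
            a = win.argmax(axis=-1)
            row.append(a)
            out_data[:, :, i, j] = np.take_along_axis(win, a[..., None], axis=-1)[..., 0]
        args.append(row)

    def backward(grad):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        bidx, cidx = np.meshgrid(np.arange(B), np.arange(C), indexing="ij")
        for i in range(out_hw):
            for j in range(out_hw):
                a = args[i][j]
                wwidth = we[j] - ws[j]
                hi = hs[i] + a // wwidth
                wi = ws[j] + a % wwidth
                np.add.at(gx, (bidx, cidx, hi, wi), grad[:, :, i, j])
        x._accumulate(gx)

    return _make(out_data, (x,), backward)
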