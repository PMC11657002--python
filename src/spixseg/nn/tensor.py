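"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` propagates gradients through the recorded graph in
reverse topological order.  The op set is exactly what the segmentation
networks and losses in this package need: broadcasted arithmetic, exp / log /
sqrt / relu / sigmoid, reductions with axis tuples, reshape / transpose /
slicing / concatenation, matmul, strided 2-D convolution and nearest-neighbour
upsampling.  float32 is used for training; float64 inputs stay float64 so the
same graph can be checked against finite differences.
"""

from __future__ import annotations

import contextlib
from typing import Sequence

import numpy as np

__all__ = ["Tensor", "no_grad", "concat", "conv2d", "stack"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference / score-only passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _result(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs from conv nets are deep
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
            if self.data.size != 1:
                raise RuntimeError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- convenience -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return self._result(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return self._result(-a.data, (a,), lambda g: a._accumulate(-g))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return self._result(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data**2), b.shape))

        return self._result(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data**exponent

        def backward(g):
            a._accumulate(g * exponent * a.data ** (exponent - 1))

        return self._result(out_data, (a,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.shape))

        return self._result(a.data @ b.data, (a, b), backward)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return self._result(out_data, (a,), lambda g: a._accumulate(g * out_data))

    def log(self):
        a = self
        return self._result(np.log(a.data), (a,), lambda g: a._accumulate(g / a.data))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return self._result(out_data, (a,), lambda g: a._accumulate(g * 0.5 / out_data))

    def sqrt_safe(self, grad_floor: float = 1e-6):
        """Exact sqrt forward; backward floors the denominator so the
        subgradient at 0 is finite (used for unsquared norms)."""
        a = self
        out_data = np.sqrt(a.data)

        def backward(g):
            a._accumulate(g * 0.5 / np.maximum(out_data, grad_floor))

        return self._result(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0
        return self._result(
            np.where(mask, a.data, 0), (a,), lambda g: a._accumulate(g * mask)
        )

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))
        return self._result(
            out_data, (a,), lambda g: a._accumulate(g * out_data * (1 - out_data))
        )

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                grad = np.broadcast_to(g, a.shape)
            elif keepdims:
                grad = np.broadcast_to(g, a.shape)
            else:
                axes = (axis,) if np.isscalar(axis) else tuple(axis)
                axes = tuple(ax % a.ndim for ax in axes)
                g_exp = np.expand_dims(g, tuple(sorted(axes)))
                grad = np.broadcast_to(g_exp, a.shape)
            a._accumulate(grad)

        return self._result(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.shape[ax % self.ndim] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max_const(self, axis=None, keepdims: bool = False) -> np.ndarray:
        """Detached maximum, e.g. the shift in a numerically stable softmax."""
        return self.data.max(axis=axis, keepdims=keepdims)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return self._result(
            a.data.reshape(shape), (a,), lambda g: a._accumulate(g.reshape(a.shape))
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)
        return self._result(
            a.data.transpose(axes), (a,), lambda g: a._accumulate(g.transpose(inv))
        )

    def __getitem__(self, idx):
        a = self

        def backward(g):
            grad = np.zeros_like(a.data)
            np.add.at(grad, idx, g)
            a._accumulate(grad)

        return self._result(a.data[idx], (a,), backward)

    def softmax(self, axis: int):
        """Numerically stable softmax along ``axis``."""
        shifted = self - self.max_const(axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def upsample2x(self):
        """Nearest-neighbour ×2 upsampling of the two trailing axes."""
        a = self
        out_data = a.data.repeat(2, axis=-2).repeat(2, axis=-1)

        def backward(g):
            shp = g.shape[:-2] + (a.shape[-2], 2, a.shape[-1], 2)
            a._accumulate(g.reshape(shp).sum(axis=(-3, -1)))

        return self._result(out_data, (a,), backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    return concat([t.reshape(t.shape[:axis] + (1,) + t.shape[axis:]) for t in tensors], axis)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._result(data, tensors, backward)


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
) -> Tensor:
    """2-D cross-correlation: ``x`` (N,C,H,W) with kernels ``w`` (F,C,kh,kw).

    Implemented as a sum of strided slices over kernel offsets; each offset is
    a single BLAS ``tensordot``, which keeps both passes fast at the patch
    sizes used here without materialising an im2col buffer.
    """
    xd = x.data
    if padding:
        xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = xd
    n, c, hp, wp = xp.shape
    f, cw, kh, kw = w.shape
    if cw != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, kernel {cw}")
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    out = np.zeros((n, f, oh, ow), dtype=np.result_type(xd, w.data))
    for a in range(kh):
        for bcol in range(kw):
            xs = xp[:, :, a : a + stride * oh : stride, bcol : bcol + stride * ow : stride]
            # (F,C)·(N,C,OH,OW) -> (F,N,OH,OW)
            out += np.tensordot(w.data[:, :, a, bcol], xs, axes=([1], [1])).transpose(
                1, 0, 2, 3
            )
    if b is not None:
        out += b.data.reshape(1, f, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if x.requires_grad:
            dxp = np.zeros_like(xp)
        for a in range(kh):
            for bcol in range(kw):
                sl = np.s_[
                    :, :, a : a + stride * oh : stride, bcol : bcol + stride * ow : stride
                ]
                if w.requires_grad:
                    xs = xp[sl]
                    dw = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
                    if w.grad is None:
                        w.grad = np.zeros_like(w.data)
                    w.grad[:, :, a, bcol] += dw.astype(w.dtype)
                if x.requires_grad:
                    dxp[sl] += np.tensordot(
                        w.data[:, :, a, bcol], g, axes=([0], [1])
                    ).transpose(1, 0, 2, 3)
        if x.requires_grad:
            if padding:
                x._accumulate(dxp[:, :, padding:-padding, padding:-padding])
            else:
                x._accumulate(dxp)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._result(out, parents, backward)
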