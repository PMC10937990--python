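"""Reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; calling :meth:`Tensor.backward` on a scalar result propagates gradients to
every tensor created with ``requires_grad=True``.  The operation set is the
minimum a small convolutional siamese network needs: broadcasting arithmetic,
matmul, reductions, elementwise nonlinearities, reshaping, 2-D convolution
(im2col), max-pooling, and ``detach`` — the stop-gradient primitive on which
the SimSiam objective depends.

Gradient correctness is established by finite-difference checks in the test
suite rather than assumed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    """An ndarray node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")
    __array_priority__ = 100.0  # so ndarray + Tensor dispatches here

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        """Stop-gradient: same values, severed from the graph."""
        return Tensor(self.data)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    # -- elementwise ----------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._make(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ----------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        return self._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(orig),)
        )

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        return self._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    # -- spatial primitives ---------------------------------------------------

    def conv2d(self, weight: "Tensor", stride: int = 1, padding: int = 0):
        """NCHW convolution by im2col; `weight` is (C_out, C_in, kH, kW)."""
        x, w = self.data, weight.data
        n, c, h, wd = x.shape
        co, ci, kh, kw = w.shape
        if ci != c:
            raise ValueError(f"channel mismatch: input {c}, weight {ci}")
        if padding:
            x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        oh = (x.shape[2] - kh) // stride + 1
        ow = (x.shape[3] - kw) // stride + 1
        cols = _im2col(x, kh, kw, stride, oh, ow)  # (n, c*kh*kw, oh*ow)
        wmat = w.reshape(co, -1)
        out_data = np.einsum("ok,nkp->nop", wmat, cols).reshape(n, co, oh, ow)

        def backward(g):
            gmat = g.reshape(n, co, -1)  # (n, co, oh*ow)
            gw = np.einsum("nop,nkp->ok", gmat, cols).reshape(w.shape)
            gcols = np.einsum("ok,nop->nkp", wmat, gmat)
            gx = _col2im(gcols, x.shape, kh, kw, stride, oh, ow)
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            return (gx, gw)

        return self._make(out_data, (self, weight), backward)

    def maxpool2d(self, size: int = 2, stride: int | None = None):
        stride = size if stride is None else stride
        x = self.data
        n, c, h, w = x.shape
        oh, ow = (h - size) // stride + 1, (w - size) // stride + 1
        cols = _im2col(x.reshape(n * c, 1, h, w), size, size, stride, oh, ow)
        cols = cols.reshape(n * c, size * size, oh * ow)
        idx = cols.argmax(axis=1)
        out_data = np.take_along_axis(cols, idx[:, None, :], axis=1)
        out_data = out_data.reshape(n, c, oh, ow)

        def backward(g):
            gcols = np.zeros_like(cols)
            np.put_along_axis(gcols, idx[:, None, :], g.reshape(n * c, 1, -1), axis=1)
            gx = _col2im(
                gcols.reshape(n * c, size * size, oh * ow),
                (n * c, 1, h, w),
                size,
                size,
                stride,
                oh,
                ow,
            )
            return (gx.reshape(n, c, h, w),)

        return self._make(out_data, (self,), backward)

    # -- autodiff driver ------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs of deep nets overflow recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                parent_grads = node._backward(g)
                for p, pg in zip(node._prev, parent_grads):
                    if not p.requires_grad or pg is None:
                        continue
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg
            if node._prev == () and node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _im2col(x, kh, kw, stride, oh, ow):
    """(n, c, h, w) -> (n, c*kh*kw, oh*ow) patch matrix."""
    n, c = x.shape[:2]
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, oh, ow),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    return windows.reshape(n, c * kh * kw, oh * ow)


def _col2im(cols, x_shape, kh, kw, stride, oh, ow):
    """Adjoint of `_im2col`: scatter-add patches back onto the image grid."""
    n, c, h, w = x_shape
    gx = np.zeros(x_shape, dtype=np.float64)
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += (
                cols[:, :, i, j]
            )
    return gx
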