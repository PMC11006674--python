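"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery for small convolutional adversarial networks: a
:class:`Tensor` wrapping an ndarray, elementwise arithmetic with broadcasting,
matrix multiplication, 2D convolution (im2col), nearest-neighbour upsampling,
channel concatenation, the usual activations, and stable softplus for
binary-cross-entropy-with-logits losses.  Gradients are accumulated by
topological traversal of the recorded graph; every op's backward pass is
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "conv2d", "upsample2x", "concat", "crop2d"]


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- graph traversal ------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other, self.data.dtype)

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.data.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, self.data.dtype)

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise NotImplementedError("divide by Tensor not supported")
        return self * (1.0 / other)

    def __pow__(self, exponent: float):
        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor(self.data**exponent, parents=(self,), backward=backward)

    def abs(self):
        def backward(g):
            self._accum(g * np.sign(self.data))

        return Tensor(np.abs(self.data), parents=(self,), backward=backward)

    # -- reductions and reshaping --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).astype(self.data.dtype))

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            parents=(self,),
            backward=backward,
        )

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=backward)

    # -- linear algebra -------------------------------------------------------
    def matmul(self, other: "Tensor"):
        def backward(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=backward)

    __matmul__ = matmul

    # -- activations ----------------------------------------------------------
    def leaky_relu(self, alpha: float = 0.2):
        mask = np.where(self.data > 0, 1.0, alpha).astype(self.data.dtype)

        def backward(g):
            self._accum(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=backward)

    def sigmoid(self):
        out = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # numerically stable

        def backward(g):
            self._accum(g * out * (1.0 - out))

        return Tensor(out, parents=(self,), backward=backward)

    def tanh(self):
        out = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out * out))

        return Tensor(out, parents=(self,), backward=backward)

    def softplus(self):
        out = np.logaddexp(0.0, self.data)

        def backward(g):
            self._accum(g * 0.5 * (1.0 + np.tanh(0.5 * self.data)))

        return Tensor(out, parents=(self,), backward=backward)


def _as_tensor(x, dtype) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """2D convolution (cross-correlation) of NCHW input with FCHW weights."""
    n, c, h, w = x.data.shape
    f, c2, kh, kw = weight.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, weight {c2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    view = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = view.shape[2], view.shape[3]
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    wmat = weight.data.reshape(f, c * kh * kw)
    out = cols @ wmat.T + bias.data
    out = out.reshape(n, ho, wo, f).transpose(0, 3, 1, 2)

    def backward(g):
        gcols = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, f)
        weight._accum((gcols.T @ cols).reshape(weight.data.shape))
        bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = (gcols @ wmat).reshape(n, ho, wo, c, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            x._accum(dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp)

    return Tensor(out, parents=(x, weight, bias), backward=backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling of an NCHW tensor."""
    n, c, h, w = x.data.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor(out, parents=(x,), backward=backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, gg in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(gg)

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=backward,
    )


def crop2d(x: Tensor, h: int, w: int) -> Tensor:
    """Crop an NCHW tensor to its top-left ``h`` x ``w`` spatial window."""
    n, c, hh, ww = x.data.shape

    def backward(g):
        gg = np.zeros_like(x.data)
        gg[:, :, :h, :w] = g
        x._accum(gg)

    return Tensor(x.data[:, :, :h, :w], parents=(x,), backward=backward)
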