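"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small dynamic-graph engine (in the micrograd tradition, extended to
ndarrays) providing exactly the operations the package's networks need:
broadcasted arithmetic, matmul, strided 2D convolution, nearest-neighbour
upsampling, reductions, reshapes, concatenation and pointwise
non-linearities. Float32 throughout; gradients accumulate in float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcasted gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph construction helper --------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out._prev = tuple(p for p in parents if isinstance(p, Tensor))
        out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(grad):
            other._accumulate(_unbroadcast(grad, other.data.shape))
            self._accumulate(_unbroadcast(grad, self.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(grad):
            self._accumulate(_unbroadcast(grad * other.data, self.data.shape))
            other._accumulate(_unbroadcast(grad * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    def __neg__(self):
        def backward(grad):
            self._accumulate(-grad)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(grad):
            self._accumulate(_unbroadcast(grad / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-grad * self.data / (other.data**2), other.data.shape)
            )

        return Tensor._make(self.data / other.data, (self, other), backward)

    __radd__ = __add__
    __rmul__ = __mul__

    def pow(self, exponent: float):
        def backward(grad):
            self._accumulate(grad * exponent * self.data ** (exponent - 1))

        return Tensor._make(self.data**exponent, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(grad):
            self._accumulate(grad * 0.5 / np.maximum(out_data, 1e-12))

        return Tensor._make(out_data, (self,), backward)

    def abs(self):
        def backward(grad):
            self._accumulate(grad * np.sign(self.data))

        return Tensor._make(np.abs(self.data), (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(grad):
            self._accumulate(grad * out_data)

        return Tensor._make(out_data, (self,), backward)

    def matmul(self, other: "Tensor"):
        def backward(grad):
            self._accumulate(grad @ other.data.T)
            other._accumulate(self.data.T @ grad)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- non-linearities -------------------------------------------------
    def leaky_relu(self, slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, slope).astype(np.float32)

        def backward(grad):
            self._accumulate(grad * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(grad):
            self._accumulate(grad * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def softplus(self):
        """log(1 + exp(x)), numerically stable."""
        out_data = np.logaddexp(0.0, self.data)

        def backward(grad):
            self._accumulate(grad / (1.0 + np.exp(-self.data)))

        return Tensor._make(out_data, (self,), backward)

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(grad):
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).astype(np.float32))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def backward(grad):
            self._accumulate(grad.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def __getitem__(self, idx):
        def backward(grad):
            g = np.zeros_like(self.data)
            g[idx] = grad
            self._accumulate(g)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- convolution -----------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor" = None, stride: int = 1, padding: int = 0):
        """2D convolution (cross-correlation), NCHW input, OIHW weight."""
        x = self.data
        w = weight.data
        n, c_in, h, w_in = x.shape
        c_out, c_in_w, kh, kw = w.shape
        assert c_in == c_in_w, "channel mismatch"
        s, p = stride, padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        oh = (xp.shape[2] - kh) // s + 1
        ow = (xp.shape[3] - kw) // s + 1
        windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        windows = windows[:, :, ::s, ::s]  # (n, c_in, oh, ow, kh, kw)
        cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c_in * kh * kw)
        w_mat = w.reshape(c_out, -1)
        out = (cols @ w_mat.T).reshape(n, oh, ow, c_out).transpose(0, 3, 1, 2)
        if bias is not None:
            out = out + bias.data.reshape(1, c_out, 1, 1)

        parents = (self, weight) + ((bias,) if bias is not None else ())

        def backward(grad):
            g = grad.transpose(0, 2, 3, 1).reshape(n * oh * ow, c_out)
            weight._accumulate((g.T @ cols).reshape(w.shape))
            if bias is not None:
                bias._accumulate(grad.sum(axis=(0, 2, 3)))
            dcols = (g @ w_mat).reshape(n, oh, ow, c_in, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[
                        :, :, :, :, i, j
                    ].transpose(0, 3, 1, 2)
            self._accumulate(dxp[:, :, p : p + h, p : p + w_in] if p else dxp)

        return Tensor._make(out.astype(np.float32), parents, backward)

    def upsample_nearest(self, factor: int):
        """Nearest-neighbour upsampling of an NCHW tensor."""
        f = factor
        out = self.data.repeat(f, axis=2).repeat(f, axis=3)
        n, c, h, w = self.data.shape

        def backward(grad):
            g = grad.reshape(n, c, h, f, w, f).sum(axis=(3, 5))
            self._accumulate(g)

        return Tensor._make(out, (self,), backward)

    # -- backprop ---------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in visited:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * grad.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(grad[tuple(sl)])

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), backward)
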