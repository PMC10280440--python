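"""Compact reverse-mode automatic differentiation on numpy arrays.

The package trains a convolutional GAN on CPU; this module supplies the
tensor type and the differentiable operations the network layers are built
from (elementwise arithmetic, matmul, 2-D convolution and transposed
convolution via im2col/col2im, reductions, activations, slicing and
concatenation).  Gradients are accumulated by topological backward
traversal, exactly the contract of mainstream deep-learning frameworks, so
layer code in :mod:`bloomcast.nn` reads conventionally.

Shapes follow the NCHW convention for image tensors.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _expit

__all__ = ["Tensor", "concat", "im2col", "col2im", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, dtype=None, name: str = ""):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=dtype if dtype is not None else None)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()
        self.name = name

    # -- plumbing -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, free_graph: bool = True):
        """Backpropagate from a scalar tensor.

        ``free_graph=True`` (default) drops the backward closures and parent
        links afterwards, breaking the reference cycles between a tensor and
        its closure so intermediate buffers are reclaimed immediately.
        """
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()
        if free_graph:
            for t in topo:
                t._backward = None
                t._parents = ()

    # -- construction helper ------------------------------------------------

    @staticmethod
    def _from_op(data: np.ndarray, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic ----------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def __add__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def backward():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.shape))

        out = Tensor._from_op(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward():
            self._accumulate(-out.grad)

        out = Tensor._from_op(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def backward():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.shape))

        out = Tensor._from_op(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        return self * other.power(-1.0)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) * self.power(-1.0)

    def power(self, p: float) -> "Tensor":
        out_data = np.power(self.data, p)

        def backward():
            self._accumulate(out.grad * p * np.power(self.data, p - 1.0))

        out = Tensor._from_op(out_data, (self,), backward)
        return out

    def sqrt(self) -> "Tensor":
        return self.power(0.5)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data @ other.data

        def backward():
            g = out.grad
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        out = Tensor._from_op(out_data, (self, other), backward)
        return out

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            g = out.grad
            if axis is not None and not keepdims:
                ax = (axis,) if isinstance(axis, int) else tuple(axis)
                g = np.expand_dims(g, ax)
            self._accumulate(np.broadcast_to(g, self.shape))

        out = Tensor._from_op(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            ax = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- activations / elementwise nonlinearities ---------------------------

    def sigmoid(self) -> "Tensor":
        s = _expit(self.data)

        def backward():
            self._accumulate(out.grad * s * (1.0 - s))

        out = Tensor._from_op(s, (self,), backward)
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)

        def backward():
            self._accumulate(out.grad * (1.0 - t * t))

        out = Tensor._from_op(t, (self,), backward)
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward():
            self._accumulate(out.grad * mask)

        out = Tensor._from_op(self.data * mask, (self,), backward)
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        scale = np.where(self.data > 0, 1.0, slope).astype(self.data.dtype)

        def backward():
            self._accumulate(out.grad * scale)

        out = Tensor._from_op(self.data * scale, (self,), backward)
        return out

    def log(self) -> "Tensor":
        def backward():
            self._accumulate(out.grad / self.data)

        out = Tensor._from_op(np.log(self.data), (self,), backward)
        return out

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)

        def backward():
            self._accumulate(out.grad * sign)

        out = Tensor._from_op(np.abs(self.data), (self,), backward)
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient is passed through inside [lo, hi] only."""
        mask = (self.data >= lo) & (self.data <= hi)

        def backward():
            self._accumulate(out.grad * mask)

        out = Tensor._from_op(np.clip(self.data, lo, hi), (self,), backward)
        return out

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward():
            self._accumulate(out.grad.reshape(old))

        out = Tensor._from_op(self.data.reshape(shape), (self,), backward)
        return out

    def narrow(self, axis: int, start: int, length: int) -> "Tensor":
        """Slice ``length`` entries from ``start`` along ``axis``."""
        idx = [slice(None)] * self.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)

        def backward():
            g = np.zeros_like(self.data)
            g[idx] = out.grad
            self._accumulate(g)

        out = Tensor._from_op(self.data[idx], (self,), backward)
        return out

    # -- convolution ---------------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor | None", stride: int,
               padding: tuple) -> "Tensor":
        """2-D cross-correlation.  weight: (Cout, Cin, kh, kw);
        padding: (top, bottom, left, right)."""
        return _conv2d(self, weight, bias, stride, padding)

    def conv_transpose2d(self, weight: "Tensor", bias: "Tensor | None",
                         stride: int, padding: tuple) -> "Tensor":
        """Transposed 2-D convolution.  weight: (Cin, Cout, kh, kw)."""
        return _conv_transpose2d(self, weight, bias, stride, padding)


# ---------------------------------------------------------------------------
# im2col / col2im (adjoint pair)
# ---------------------------------------------------------------------------

def im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: tuple) -> np.ndarray:
    """Unfold (N, C, H, W) into (N, C*kh*kw, OH*OW) patches."""
    pt, pb, pl, pr = padding
    if any(padding):
        x = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    n, c, hp, wp = x.shape
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    out = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        i_end = i + stride * oh
        for j in range(kw):
            out[:, :, i, j] = x[:, :, i:i_end:stride, j:j + stride * ow:stride]
    return out.reshape(n, c * kh * kw, oh * ow)


def col2im(cols: np.ndarray, x_shape: tuple, kh: int, kw: int, stride: int,
           padding: tuple) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patches back to (N, C, H, W)."""
    n, c, h, w = x_shape
    pt, pb, pl, pr = padding
    hp, wp = h + pt + pb, w + pl + pr
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        i_end = i + stride * oh
        for j in range(kw):
            out[:, :, i:i_end:stride, j:j + stride * ow:stride] += cols[:, :, i, j]
    return out[:, :, pt:hp - pb, pl:wp - pr]


def _conv2d(x: Tensor, weight: Tensor, bias, stride: int, padding: tuple) -> Tensor:
    n, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input has {cin}, kernel expects {cin_w}")
    pt, pb, pl, pr = padding
    oh = (h + pt + pb - kh) // stride + 1
    ow = (w + pl + pr - kw) // stride + 1
    cols = im2col(x.data, kh, kw, stride, padding)          # (N, Cin*k*k, L)
    w2 = weight.data.reshape(cout, -1)
    out_data = np.matmul(w2, cols).reshape(n, cout, oh, ow)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)
    # patches are recomputed in backward: retaining them across a deep graph
    # costs far more memory than the recompute costs time
    del cols

    parents = (x, weight) + ((bias,) if bias is not None else ())

    def backward():
        g = out.grad.reshape(n, cout, oh * ow)
        if bias is not None and bias.requires_grad:
            bias._accumulate(out.grad.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            cols_b = im2col(x.data, kh, kw, stride, padding)
            gw = np.matmul(g, cols_b.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(gw.reshape(weight.shape))
        if x.requires_grad:
            dcols = np.matmul(w2.T, g)                      # (N, Cin*k*k, L)
            x._accumulate(col2im(dcols, x.shape, kh, kw, stride, padding))

    out = Tensor._from_op(out_data, parents, backward)
    return out


def _conv_transpose2d(x: Tensor, weight: Tensor, bias, stride: int,
                      padding: tuple) -> Tensor:
    n, cin, h, w = x.shape
    cin_w, cout, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(
            f"conv_transpose2d channel mismatch: input has {cin}, kernel expects {cin_w}")
    pt, pb, pl, pr = padding
    oh = (h - 1) * stride + kh - pt - pb
    ow = (w - 1) * stride + kw - pl - pr
    x_mat = x.data.reshape(n, cin, h * w)
    w2 = weight.data.reshape(cin, cout * kh * kw)
    cols = np.matmul(w2.T, x_mat)                           # (N, Cout*k*k, H*W)
    out_data = col2im(cols, (n, cout, oh, ow), kh, kw, stride, padding)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) + ((bias,) if bias is not None else ())

    def backward():
        if bias is not None and bias.requires_grad:
            bias._accumulate(out.grad.sum(axis=(0, 2, 3)))
        gcols = im2col(out.grad, kh, kw, stride, padding)   # (N, Cout*k*k, H*W)
        if weight.requires_grad:
            gw = np.matmul(x_mat, gcols.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(gw.reshape(weight.shape))
        if x.requires_grad:
            gx = np.matmul(w2, gcols)                       # (N, Cin, H*W)
            x._accumulate(gx.reshape(x.shape))

    out = Tensor._from_op(out_data, parents, backward)
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, start, size in zip(tensors, offsets[:-1], sizes):
            if t.requires_grad:
                idx = [slice(None)] * out_data.ndim
                idx[axis] = slice(int(start), int(start + size))
                t._accumulate(out.grad[tuple(idx)])

    out = Tensor._from_op(out_data, tuple(tensors), backward)
    return out
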