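"""Reverse-mode automatic differentiation on numpy arrays.

A compact tape-based autograd core sized for the 2D segmentation networks in
this package: dense blocks are channel concatenations of small convolutions,
so the primitive set is ``conv2d`` (im2col), ``batch_norm2d``, ``relu``,
``avg_pool2d``, 2x2 stride-2 transposed convolution, channel ``concat`` /
``narrow``, ``softmax`` and elementwise arithmetic.  Every primitive's
gradient is checked against central finite differences in the test suite.

Arrays follow the NCHW layout (batch, channel, height, width) throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "narrow",
    "conv2d",
    "conv_transpose2x2",
    "avg_pool2d",
    "batch_norm2d",
    "softmax",
    "relu",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            buf = _alloc(self.data.shape, self.data.dtype)
            np.copyto(buf, grad)
            self.grad = buf
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion limits
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- elementwise arithmetic ---------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def bwd(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(self.data**exponent, (self,), bwd)

    # -- reductions and shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        def bwd(g):
            self._accumulate(g.reshape(self.shape))

        return Tensor._make(self.data.reshape(*shape), (self,), bwd)

    # -- nonlinear primitives --------------------------------------------------

    def log(self):
        def bwd(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through the unclamped region."""
        mask = (self.data > lo) & (self.data < hi)

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor._make(np.where(mask, self.data, 0.0), (self,), bwd)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def relu(x: Tensor) -> Tensor:
    return x.relu()


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along ``axis``; the backward pass splits the gradient."""
    tensors = list(tensors)  # snapshot: callers may mutate their list afterwards
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(int(lo), int(hi))
                t._accumulate(g[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd
    )


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Slice ``length`` entries from ``start`` along ``axis``."""
    idx = [slice(None)] * x.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)

    def bwd(g):
        full = np.zeros_like(x.data)
        full[idx] = g
        x._accumulate(full)

    return Tensor._make(x.data[idx], (x,), bwd)


# -- convolution -------------------------------------------------------------


_POOL: dict[tuple[int, str], list[np.ndarray]] = {}
_POOL_BUCKET_MAX = 64


def _alloc(shape, dtype) -> np.ndarray:
    """Pooled array allocation for the large convolution workspaces.

    Repeatedly allocating and freeing tens-of-MB patch matrices makes the
    allocator return pages to the OS and fault them back in every step,
    which dominates runtime on a single core.  The pool keeps flat buffers
    keyed by size and hands out reshaped views; a buffer is free again when
    only the pool references it (checked via the refcount), which the
    backward closures naturally guarantee once a step's graph is dropped.
    """
    import sys

    size = int(np.prod(shape))
    key = (size, np.dtype(dtype).str)
    bucket = _POOL.setdefault(key, [])
    for arr in bucket:
        if sys.getrefcount(arr) == 3:  # bucket entry + loop var + getrefcount arg
            return arr.reshape(shape)
    arr = np.empty(size, dtype=dtype)
    if len(bucket) < _POOL_BUCKET_MAX:
        bucket.append(arr)
    return arr.reshape(shape)


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (C*kh*kw, N*OH*OW) patch matrix for stride-1 convolution.

    Channel-major layout so both the forward product and the two backward
    products are single large GEMMs rather than batched thin ones.
    """
    n, c, h, w = x.shape
    # one cheap CNHW transpose up front keeps the kernel-offset gathers
    # below in natural memory order
    xt = _alloc((c, n, h + 2 * pad, w + 2 * pad), x.dtype)
    if pad:
        xt[:] = 0.0
        xt[:, :, pad : pad + h, pad : pad + w] = x.transpose(1, 0, 2, 3)
    else:
        xt[:] = x.transpose(1, 0, 2, 3)
    oh = h + 2 * pad - kh + 1
    ow = w + 2 * pad - kw + 1
    if kh == kw == 1:
        return xt.reshape(c, n * oh * ow)
    cols = _alloc((c, kh, kw, n, oh, ow), x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, i, j] = xt[:, :, i : i + oh, j : j + ow]
    return cols.reshape(c * kh * kw, n * oh * ow)


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back onto the image)."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh, ow = hp - kh + 1, wp - kw + 1
    xt = _alloc((c, n, hp, wp), cols.dtype)
    xt[:] = 0.0
    cols = cols.reshape(c, kh, kw, n, oh, ow)
    for i in range(kh):
        for j in range(kw):
            xt[:, :, i : i + oh, j : j + ow] += cols[:, i, j]
    if pad:
        xt = xt[:, :, pad:-pad, pad:-pad]
    out = _alloc((n, c, h, w), cols.dtype)
    out[:] = xt.transpose(1, 0, 2, 3)
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, pad: int) -> Tensor:
    """Stride-1 2D convolution, NCHW; ``weight`` is (F, C, KH, KW)."""
    f, c, kh, kw = weight.shape
    n = x.shape[0]
    oh = x.shape[2] + 2 * pad - kh + 1
    ow = x.shape[3] + 2 * pad - kw + 1
    cols = _im2col(x.data, kh, kw, pad)  # (C*kh*kw, N*L)
    wmat = weight.data.reshape(f, c * kh * kw)
    fout = _alloc((f, n * oh * ow), x.data.dtype)
    np.matmul(wmat, cols, out=fout)  # one GEMM
    if bias is not None:
        fout += bias.data[:, None]
    out = _alloc((n, f, oh, ow), x.data.dtype)
    out[:] = fout.reshape(f, n, oh, ow).transpose(1, 0, 2, 3)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        gmat = _alloc((f, n, oh, ow), g.dtype)
        gmat[:] = g.transpose(1, 0, 2, 3)
        gmat = gmat.reshape(f, n * oh * ow)
        if weight.requires_grad:
            weight._accumulate((gmat @ cols.T).reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(gmat.sum(axis=1))
        if x.requires_grad:
            dcols = wmat.T @ gmat
            x._accumulate(_col2im(dcols, x.shape, kh, kw, pad))

    return Tensor._make(out, parents, bwd)


def conv_transpose2x2(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """2x2 stride-2 transposed convolution (exact 2x upsampling).

    ``weight`` is (C_in, C_out, 2, 2); output spatial dims are doubled.
    """
    n, c, h, w = x.shape
    f = weight.shape[1]
    xmat = x.data.reshape(n, c, h * w)
    out = np.zeros((n, f, 2 * h, 2 * w), dtype=x.data.dtype)
    for i in range(2):
        for j in range(2):
            out[:, :, i::2, j::2] = np.matmul(
                weight.data[:, :, i, j].T, xmat
            ).reshape(n, f, h, w)
    if bias is not None:
        out += bias.data.reshape(1, f, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        gsub = {
            (i, j): np.ascontiguousarray(g[:, :, i::2, j::2]).reshape(n, f, h * w)
            for i in range(2)
            for j in range(2)
        }
        if weight.requires_grad:
            dw = np.empty_like(weight.data)
            for (i, j), gm in gsub.items():
                dw[:, :, i, j] = np.matmul(xmat, gm.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(dw)
        if x.requires_grad:
            dx = np.zeros((n, c, h * w), dtype=x.data.dtype)
            for (i, j), gm in gsub.items():
                dx += np.matmul(weight.data[:, :, i, j], gm)
            x._accumulate(dx.reshape(x.shape))

    return Tensor._make(out, parents, bwd)


def avg_pool2d(x: Tensor) -> Tensor:
    """2x2 average pooling, stride 2; spatial dims must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"avg_pool2d requires even spatial dims, got {h}x{w}")
    out = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def bwd(g):
        dx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        x._accumulate(dx)

    return Tensor._make(out, (x,), bwd)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization with running statistics (NCHW)."""
    axes = (0, 2, 3)
    c = x.shape[1]
    gshape = (1, c, 1, 1)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = (1.0 / np.sqrt(var + eps)).astype(x.data.dtype)
    # fused affine: out = a*x + b with a = gamma/std, b = beta - a*mean
    a = (gamma.data * inv_std).reshape(gshape)
    b = (beta.data - gamma.data * inv_std * mean).reshape(gshape)
    out = a * x.data + b

    def _xhat():
        return (x.data - mean.reshape(gshape)) * inv_std.reshape(gshape)

    def bwd(g):
        xh = _xhat() if (gamma.requires_grad or (x.requires_grad and training)) else None
        if gamma.requires_grad:
            gamma._accumulate((g * xh).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if x.requires_grad:
            gi = (gamma.data * inv_std).reshape(gshape)
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                sum_g = g.sum(axis=axes, keepdims=True)
                sum_gx = (g * xh).sum(axis=axes, keepdims=True)
                dx = gi * (g - sum_g / m - xh * sum_gx / m)
            else:
                dx = gi * g
            x._accumulate(dx)

    return Tensor._make(out, (x, gamma, beta), bwd)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accumulate(y * (g - dot))

    return Tensor._make(y, (x,), bwd)
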