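"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package needs gradients through two very different computations: the
variational convolutional segmentation network and the Hamiltonian LDDMM
surface flow.  Both are expressed as compositions of a small set of array
primitives, so a compact tape-based autodiff engine is sufficient.  Only the
primitives actually used by the models are implemented; each op stores just
what its backward pass needs.

Conventions
-----------
* ``Tensor`` wraps an ``np.ndarray``; ``requires_grad`` marks leaves that
  accumulate gradients.
* ``backward()`` may only be called on a scalar tensor.
* Convolutions are stride-1 with symmetric "same" zero padding; spatial
  resampling is done with explicit pooling / upsampling primitives.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "concatenate",
    "conv3d",
    "maxpool3d",
    "upsample3d",
    "spmm",
    "Adam",
]

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


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(float)
    return Tensor(arr, requires_grad=False)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------- basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return float(self.data)

    def numpy(self):
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------ backward
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            if t is not self and t._parents:
                t.grad = None  # free intermediate gradients

    # ------------------------------------------------------------- helpers
    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, copy=True)
        else:
            self.grad = self.grad + g

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # ---------------------------------------------------------- arithmetic
    def __add__(self, other):
        a, b = self, _as_tensor(other)

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __sub__(self, other):
        a, b = self, _as_tensor(other)

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g, b.shape))

        return Tensor._make(a.data - b.data, (a, b), bw)

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __mul__(self, other):
        a, b = self, _as_tensor(other)

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, _as_tensor(other)

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __neg__(self):
        a = self

        def bw(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), bw)

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        a = self

        def bw(g):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(a.data ** p, (a,), bw)

    def __matmul__(self, other):
        a, b = self, _as_tensor(other)

        def bw(g):
            if a.requires_grad:
                if b.data.ndim == 1:
                    a._accum(np.outer(g, b.data) if a.data.ndim == 2 else g * b.data)
                else:
                    ga = g @ np.swapaxes(b.data, -1, -2)
                    a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                if a.data.ndim == 1:
                    b._accum(np.outer(a.data, g) if b.data.ndim == 2 else g * a.data)
                else:
                    gb = np.swapaxes(a.data, -1, -2) @ g
                    b._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(a.data @ b.data, (a, b), bw)

    # --------------------------------------------------------- elementwise
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bw)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bw(g):
            a._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), bw)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))

        def bw(g):
            a._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), bw)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bw(g):
            a._accum(g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (a,), bw)

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), bw)

    def softplus(self):
        """log(1 + e^x), numerically stable."""
        a = self
        out_data = np.logaddexp(0.0, a.data)

        def bw(g):
            a._accum(g / (1.0 + np.exp(-np.clip(a.data, -60, 60))))

        return Tensor._make(out_data, (a,), bw)

    # ---------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        a = self

        def bw(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.shape))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # ------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self

        def bw(g):
            a._accum(g.reshape(a.shape))

        return Tensor._make(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes):
        a = self
        axes = axes or None
        if axes is not None and len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = None if axes is None else tuple(np.argsort(axes))

        def bw(g):
            a._accum(g.transpose(inv) if inv is not None else g.transpose())

        return Tensor._make(a.data.transpose(axes) if axes else a.data.T, (a,), bw)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        a = self

        def bw(g):
            gx = np.zeros(a.shape, dtype=g.dtype)
            np.add.at(gx, idx, g)
            a._accum(gx)

        return Tensor._make(a.data[idx], (a,), bw)


def concatenate(tensors, axis=0):
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
    )


# ------------------------------------------------------------------ conv ops
# Reused scratch buffers for the convolution work arrays.  Allocating
# hundreds of MB afresh every layer is dominated by page faults on a
# memory-bandwidth-bound host, so buffers are pooled by shape/dtype and
# refilled in place.  Single-threaded use only.
_workspace: dict = {}


def _buf(tag: str, shape: tuple, dtype) -> tuple:
    """Pooled uninitialized buffer; second return marks a fresh allocation."""
    key = (tag, shape, np.dtype(dtype))
    b = _workspace.get(key)
    fresh = b is None
    if fresh:
        b = np.empty(shape, dtype)
        _workspace[key] = b
    return b, fresh


def _padded(data: np.ndarray, p: int, tag="pad") -> np.ndarray:
    """Zero-padded copy of (..., D, H, W) using a pooled buffer.

    The border is zeroed only when the buffer is new; every user writes the
    full interior, so stale borders can never leak.  Pass a unique ``tag``
    (e.g. keyed to a layer) when the padded array must survive until the
    backward pass instead of being scratch.
    """
    shape = data.shape[:-3] + tuple(n + 2 * p for n in data.shape[-3:])
    out, fresh = _buf(tag, shape, data.dtype)
    if fresh:
        out[:] = 0
    out[..., p:-p, p:-p, p:-p] = data
    return out


def _im2col(xp_n: np.ndarray, k: int, dilation: int, D: int, H: int,
            W: int) -> np.ndarray:
    """(Cin, Dp, Hp, Wp) -> (Cin*k^3, D*H*W) patch matrix in a pooled buffer.

    Built by k^3 direct strided slice copies, which is markedly faster than
    transposing a sliding-window view.
    """
    Cin = xp_n.shape[0]
    cols, _ = _buf("cols", (Cin, k ** 3, D, H, W), xp_n.dtype)
    idx = 0
    for i in range(k):
        for j in range(k):
            for l in range(k):
                cols[:, idx] = xp_n[:, i * dilation:i * dilation + D,
                                    j * dilation:j * dilation + H,
                                    l * dilation:l * dilation + W]
                idx += 1
    return cols.reshape(Cin * k ** 3, D * H * W)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """3D multi-channel convolution (cross-correlation), stride 1, 'same' padding.

    x: (N, C_in, D, H, W); w: (C_out, C_in, k, k, k) with odd cubic k; b:
    (C_out,).  Forward and both gradients are im2col + GEMM; the input
    gradient is the transpose convolution, i.e. a forward pass with the
    spatially flipped, channel-transposed kernel.  1x1x1 kernels skip the
    im2col entirely.
    """
    x = _as_tensor(x)
    w = _as_tensor(w)
    N, Cin, D, H, W = x.shape
    Cout, Cin2, kd, kh, kw = w.shape
    if Cin != Cin2:
        raise ValueError("channel mismatch")
    if not (kd == kh == kw):
        raise ValueError("kernels must be cubic")
    if kd % 2 == 0:
        raise ValueError("kernel size must be odd")
    k = kd
    p = dilation * (k // 2)
    nvox = D * H * W
    w2 = w.data.reshape(Cout, Cin * k ** 3)
    # the padded input must survive until backward; key its buffer to the
    # weight tensor so each layer reuses its own slot across steps (a weight
    # used twice in one graph would need distinct tags — not the case here)
    xp = None if k == 1 else _padded(x.data, p, tag=("xp", id(w)))
    out = np.empty((N, Cout, D, H, W), dtype=x.dtype)
    for n in range(N):
        cols = x.data[n].reshape(Cin, nvox) if k == 1 \
            else _im2col(xp[n], k, dilation, D, H, W)
        np.matmul(w2, cols, out=out[n].reshape(Cout, nvox))
    if b is not None:
        b = _as_tensor(b)
        out += b.data.astype(x.dtype)[None, :, None, None, None]
        parents = (x, w, b)
    else:
        parents = (x, w)

    def bw(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            gw2 = np.zeros((Cout, Cin * k ** 3), dtype=g.dtype)
            for n in range(N):
                cols = x.data[n].reshape(Cin, nvox) if k == 1 \
                    else _im2col(xp[n], k, dilation, D, H, W)
                gw2 += g[n].reshape(Cout, nvox) @ cols.T
            w._accum(gw2.reshape(w.shape))
        if x.requires_grad:
            if k == 1:
                gx = np.einsum("oc,nov->ncv", w.data.reshape(Cout, Cin),
                               g.reshape(N, Cout, nvox)).reshape(x.shape)
            else:
                wT = np.ascontiguousarray(
                    w.data.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
                ).reshape(Cin, Cout * k ** 3)
                gp = _padded(g, p)
                gx, _ = _buf("gx", x.shape, g.dtype)
                for n in range(N):
                    gcols = _im2col(gp[n], k, dilation, D, H, W)
                    np.matmul(wT, gcols, out=gx[n].reshape(Cin, nvox))
            x._accum(gx)

    return Tensor._make(out, parents, bw)


def corr3d_single(x: Tensor, w: Tensor) -> Tensor:
    """Single-channel 3D correlation with one (k,k,k) kernel, 'same' zero pad.

    x: (N, 1, D, H, W); w: (k, k, k) with odd k.  Used by the LoG stream,
    where kernels are large (up to 11^3) and an offset loop would be slow;
    scipy's correlate handles the heavy lifting in both passes.
    """
    from scipy.ndimage import convolve as nd_convolve, correlate as nd_correlate
    from scipy.signal import correlate as sig_correlate

    x = _as_tensor(x)
    w = _as_tensor(w)
    if w.data.shape[0] % 2 == 0:
        raise ValueError("kernel size must be odd")
    N = x.shape[0]
    out = np.stack([nd_correlate(x.data[n, 0], w.data, mode="constant")
                    for n in range(N)])[:, None]

    def bw(g):
        if w.requires_grad:
            p = w.data.shape[0] // 2
            gw = np.zeros_like(w.data)
            for n in range(N):
                xp = np.pad(x.data[n, 0], p)
                gw += sig_correlate(xp, g[n, 0], mode="valid")
            w._accum(gw)
        if x.requires_grad:
            gx = np.stack([nd_convolve(g[n, 0], w.data, mode="constant")
                           for n in range(N)])[:, None]
            x._accum(gx)

    return Tensor._make(out, (x, w), bw)


def maxpool3d(x: Tensor, factor: int = 2) -> Tensor:
    """Non-overlapping max pooling; spatial dims must be divisible by factor."""
    x = _as_tensor(x)
    N, C, D, H, W = x.shape
    f = factor
    if D % f or H % f or W % f:
        raise ValueError("spatial dimensions must be divisible by the pool factor")
    blocks = x.data.reshape(N, C, D // f, f, H // f, f, W // f, f)
    out = blocks.max(axis=(3, 5, 7))

    def bw(g):
        mask = blocks == out[:, :, :, None, :, None, :, None]
        counts = mask.sum(axis=(3, 5, 7), keepdims=True)
        gb = mask * (g[:, :, :, None, :, None, :, None] / counts)
        x._accum(gb.reshape(N, C, D, H, W))

    return Tensor._make(out, (x,), bw)


def upsample3d(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling of the three spatial dims."""
    x = _as_tensor(x)
    f = factor
    out = x.data.repeat(f, axis=2).repeat(f, axis=3).repeat(f, axis=4)
    N, C, D, H, W = x.shape

    def bw(g):
        gb = g.reshape(N, C, D, f, H, f, W, f).sum(axis=(3, 5, 7))
        x._accum(gb)

    return Tensor._make(out, (x,), bw)


def spmm(A, x: Tensor) -> Tensor:
    """Product of a constant (sparse or dense) matrix with a tensor."""
    x = _as_tensor(x)

    def bw(g):
        x._accum(A.T @ g)

    return Tensor._make(A @ x.data, (x,), bw)


# ------------------------------------------------------------------ optimizer
class Adam:
    """Adam optimizer over a list of leaf Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros(p.shape, dtype=p.data.dtype) for p in self.params]
        self.v = [np.zeros(p.shape, dtype=p.data.dtype) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
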