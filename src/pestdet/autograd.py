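"""Reverse-mode automatic differentiation over NumPy arrays.

This is the numerical substrate of the detector: a small tape-based
autodiff engine whose primitives cover exactly what a single-stage
convolutional detector needs — 2-D convolution, batch normalisation,
pooling, nearest-neighbour upsampling, space-to-depth, elementwise
algebra and the logistic losses.  Convolutions are evaluated by the
shift-and-GEMM scheme: for every kernel offset ``(i, j)`` a strided
slice of the (padded) input is contracted against the corresponding
kernel slab with one matrix product, so both the forward pass and the
two backward passes reduce to ``k*k`` BLAS calls and are exact.

All arithmetic is float32.  Gradients are accumulated by a topological
sweep over the recorded graph; ``no_grad`` disables recording for
inference-only passes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "minimum",
    "maximum",
    "conv2d",
    "linear",
    "batch_norm",
    "max_pool2d",
    "upsample_nearest2x",
    "space_to_depth",
    "global_avg_pool",
    "bce_with_logits",
]


class _GradMode:
    enabled = True


class _FlopLog:
    """When ``items`` is a list, forward primitives append
    ``(kind, macs, elementwise_flops)`` entries (complexity accounting)."""
    items: list | None = None


class flop_recorder:
    def __enter__(self):
        self._prev = _FlopLog.items
        _FlopLog.items = []
        return _FlopLog.items

    def __exit__(self, *exc):
        _FlopLog.items = self._prev
        return False


class no_grad:
    """Context manager disabling graph recording."""

    def __enter__(self):
        self._prev = _GradMode.enabled
        _GradMode.enabled = False
        return self

    def __exit__(self, *exc):
        _GradMode.enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helper -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GradMode.enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- bookkeeping ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accumulate(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- elementwise algebra -------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: a._accumulate(-g))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._make(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p

        def bwd(g):
            a._accumulate(g * p * a.data ** (p - 1.0))

        return Tensor._make(out_data, (a,), bwd)

    # -- unary functions -----------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: a._accumulate(g * out_data))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: a._accumulate(g / a.data))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._make(out_data, (a,),
                            lambda g: a._accumulate(g * 0.5 / out_data))

    def sigmoid(self):
        a = self
        s = _sigmoid(a.data)
        if _FlopLog.items is not None:
            _FlopLog.items.append(("sigmoid", 0, 4 * a.data.size))
        return Tensor._make(s, (a,), lambda g: a._accumulate(g * s * (1.0 - s)))

    def silu(self):
        """x * sigmoid(x) — the detector's default activation."""
        a = self
        s = _sigmoid(a.data)
        out_data = a.data * s
        if _FlopLog.items is not None:
            _FlopLog.items.append(("silu", 0, 4 * a.data.size))

        def bwd(g):
            a._accumulate(g * (s * (1.0 + a.data * (1.0 - s))))

        return Tensor._make(out_data, (a,), bwd)

    def relu(self):
        a = self
        mask = a.data > 0
        if _FlopLog.items is not None:
            _FlopLog.items.append(("relu", 0, a.data.size))
        return Tensor._make(a.data * mask, (a,), lambda g: a._accumulate(g * mask))

    def arctan(self):
        a = self
        return Tensor._make(np.arctan(a.data), (a,),
                            lambda g: a._accumulate(g / (1.0 + a.data * a.data)))

    def clamp(self, lo=None, hi=None):
        a = self
        out_data = np.clip(a.data, lo, hi)
        inside = np.ones_like(a.data, dtype=bool)
        if lo is not None:
            inside &= a.data >= lo
        if hi is not None:
            inside &= a.data <= hi
        return Tensor._make(out_data, (a,), lambda g: a._accumulate(g * inside))

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).astype(np.float32))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(gg, a.shape).astype(np.float32))

        return Tensor._make(out_data, (a,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else (
            np.prod([self.shape[ax] for ax in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape surgery ---------------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._make(a.data.reshape(shape), (a,),
                            lambda g: a._accumulate(g.reshape(a.shape)))

    def moveaxis(self, src, dst):
        a = self
        return Tensor._make(np.moveaxis(a.data, src, dst), (a,),
                            lambda g: a._accumulate(np.moveaxis(g, dst, src)))

    def __getitem__(self, idx):
        a = self
        out_data = a.data[idx]

        def bwd(g):
            buf = np.zeros_like(a.data)
            np.add.at(buf, idx, g)
            a._accumulate(buf)

        return Tensor._make(out_data, (a,), bwd)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# -- n-ary ops ----------------------------------------------------------------

def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, bwd)


def minimum(a, b) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)
    b = b if isinstance(b, Tensor) else Tensor(b)
    take_a = a.data <= b.data  # ties route the gradient to the first argument

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * take_a, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * ~take_a, b.shape))

    return Tensor._make(np.minimum(a.data, b.data), (a, b), bwd)


def maximum(a, b) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)
    b = b if isinstance(b, Tensor) else Tensor(b)
    take_a = a.data >= b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * take_a, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * ~take_a, b.shape))

    return Tensor._make(np.maximum(a.data, b.data), (a, b), bwd)


# -- convolution --------------------------------------------------------------

def _conv_out(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, OIHW kernels."""
    B, C, H, W = x.shape
    O, Ci, kh, kw = w.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, kernel expects {Ci}")
    Ho, Wo = _conv_out(H, kh, stride, padding), _conv_out(W, kw, stride, padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    # channels-last for GEMM-friendly contractions
    xp_cl = np.ascontiguousarray(np.moveaxis(xp, 1, 3))
    y_cl = np.zeros((B, Ho, Wo, O), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            xs = xp_cl[:, i:i + stride * Ho:stride, j:j + stride * Wo:stride, :]
            y_cl += (np.ascontiguousarray(xs).reshape(-1, C)
                     @ w.data[:, :, i, j].T).reshape(B, Ho, Wo, O)
    y = np.moveaxis(y_cl, 3, 1)
    if b is not None:
        y = y + b.data.reshape(1, O, 1, 1)
    if _FlopLog.items is not None:
        macs = kh * kw * C * O * Ho * Wo * B
        _FlopLog.items.append(("conv2d", macs, (O * Ho * Wo * B) if b is not None else 0))

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        g_cl = np.ascontiguousarray(np.moveaxis(g, 1, 3))  # B,Ho,Wo,O
        g_flat = g_cl.reshape(-1, O)
        if b is not None and b.requires_grad:
            b._accumulate(g_flat.sum(axis=0))
        if w.requires_grad:
            dw = np.zeros_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    xs = xp_cl[:, i:i + stride * Ho:stride,
                               j:j + stride * Wo:stride, :]
                    dw[:, :, i, j] = g_flat.T @ np.ascontiguousarray(xs).reshape(-1, C)
            w._accumulate(dw)
        if x.requires_grad:
            dxp_cl = np.zeros_like(xp_cl)
            for i in range(kh):
                for j in range(kw):
                    dxs = (g_flat @ w.data[:, :, i, j]).reshape(B, Ho, Wo, C)
                    dxp_cl[:, i:i + stride * Ho:stride,
                           j:j + stride * Wo:stride, :] += dxs
            dxp = np.moveaxis(dxp_cl, 3, 1)
            if padding:
                dxp = dxp[:, :, padding:padding + H, padding:padding + W]
            x._accumulate(np.ascontiguousarray(dxp))

    return Tensor._make(y, parents, bwd)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """y = x @ w.T + b for 2-D x (N, Cin) and w (Cout, Cin)."""
    y = x.data @ w.data.T
    if b is not None:
        y = y + b.data
    if _FlopLog.items is not None:
        _FlopLog.items.append(("linear", x.data.shape[0] * w.data.size,
                               y.size if b is not None else 0))
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=0))
        if w.requires_grad:
            w._accumulate(g.T @ x.data)
        if x.requires_grad:
            x._accumulate(g @ w.data)

    return Tensor._make(y, parents, bwd)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1, eps: float = 1e-5,
               per_sample: bool = False) -> Tensor:
    """Normalisation over all axes except channel.

    Standard behaviour: batch statistics during training (running
    estimates updated in place), running statistics at inference.  With
    ``per_sample`` (4-D input only) each sample is normalised by its own
    spatial statistics in both modes — instance-style normalisation with
    no train/eval gap, the configuration used for very small training
    batches.
    """
    cshape = [1] * x.ndim
    cshape[1] = x.shape[1]
    if per_sample and x.ndim == 4:
        axes = (2, 3)
        mu = x.data.mean(axis=axes, keepdims=True)
        var = x.data.var(axis=axes, keepdims=True)
        use_current = True
    else:
        axes = tuple(ax for ax in range(x.ndim) if ax != 1)
        use_current = training
        if training:
            mu_c = x.data.mean(axis=axes)
            var_c = x.data.var(axis=axes)
            n = x.data.size / x.shape[1]
            running_mean *= (1.0 - momentum)
            running_mean += momentum * mu_c
            running_var *= (1.0 - momentum)
            running_var += momentum * var_c * (n / max(n - 1.0, 1.0))  # unbiased
            mu, var = mu_c.reshape(cshape), var_c.reshape(cshape)
        else:
            mu = running_mean.reshape(cshape)
            var = running_var.reshape(cshape)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    y = gamma.data.reshape(cshape) * xhat + beta.data.reshape(cshape)
    if _FlopLog.items is not None:
        _FlopLog.items.append(("batch_norm", 0, 2 * x.data.size))

    def bwd(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=tuple(ax for ax in range(x.ndim)
                                              if ax != 1)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=tuple(
                ax for ax in range(x.ndim) if ax != 1)))
        if x.requires_grad:
            gs = gamma.data.reshape(cshape) * inv_std
            if use_current and (x.requires_grad or training):
                gm = g.mean(axis=axes, keepdims=True)
                gxm = (g * xhat).mean(axis=axes, keepdims=True)
                x._accumulate(gs * (g - gm - xhat * gxm))
            else:
                x._accumulate(gs * g)

    return Tensor._make(y, (x, gamma, beta), bwd)


def max_pool2d(x: Tensor, kernel: int, stride: int = 1,
               padding: int | None = None) -> Tensor:
    """Max pooling; default padding keeps the spatial size at stride 1
    (the SPP configuration)."""
    if padding is None:
        padding = kernel // 2
    B, C, H, W = x.shape
    Ho, Wo = _conv_out(H, kernel, stride, padding), _conv_out(W, kernel, stride, padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, :, :][:, :, :Ho, :Wo]
    flat = win.reshape(B, C, Ho, Wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    if _FlopLog.items is not None:
        _FlopLog.items.append(("max_pool2d", 0, (kernel * kernel - 1) * arg.size))

    def bwd(g):
        dxp = np.zeros_like(xp)
        ki, kj = np.unravel_index(arg, (kernel, kernel))
        bb, cc, ii, jj = np.indices(arg.shape, sparse=False)
        rows = ii * stride + ki
        cols = jj * stride + kj
        np.add.at(dxp, (bb, cc, rows, cols), g)
        if padding:
            dxp = dxp[:, :, padding:padding + H, padding:padding + W]
        x._accumulate(dxp)

    return Tensor._make(y.astype(np.float32), (x,), bwd)


def upsample_nearest2x(x: Tensor) -> Tensor:
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bwd(g):
        B, C, H2, W2 = g.shape
        x._accumulate(g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)))

    return Tensor._make(y, (x,), bwd)


def space_to_depth(x: Tensor) -> Tensor:
    """2x2 space-to-depth: (B, C, H, W) -> (B, 4C, H/2, W/2).

    The four channel groups are the four pixel phases
    (even/even, odd/even, even/odd, odd/odd rows/columns), so the map is a
    permutation of the input — lossless and exactly invertible."""
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError("space_to_depth needs even spatial dimensions")
    y = np.concatenate([x.data[:, :, 0::2, 0::2], x.data[:, :, 1::2, 0::2],
                        x.data[:, :, 0::2, 1::2], x.data[:, :, 1::2, 1::2]], axis=1)

    def bwd(g):
        dx = np.zeros_like(x.data)
        dx[:, :, 0::2, 0::2] = g[:, :C]
        dx[:, :, 1::2, 0::2] = g[:, C:2 * C]
        dx[:, :, 0::2, 1::2] = g[:, 2 * C:3 * C]
        dx[:, :, 1::2, 1::2] = g[:, 3 * C:]
        x._accumulate(dx)

    return Tensor._make(y, (x,), bwd)


def depth_to_space(y: np.ndarray) -> np.ndarray:
    """Inverse of :func:`space_to_depth` on plain arrays (used to verify
    losslessness)."""
    B, C4, Hh, Wh = y.shape
    C = C4 // 4
    x = np.zeros((B, C, Hh * 2, Wh * 2), dtype=y.dtype)
    x[:, :, 0::2, 0::2] = y[:, :C]
    x[:, :, 1::2, 0::2] = y[:, C:2 * C]
    x[:, :, 0::2, 1::2] = y[:, 2 * C:3 * C]
    x[:, :, 1::2, 1::2] = y[:, 3 * C:]
    return x


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over the spatial grid: (B, C, H, W) -> (B, C)."""
    B, C, H, W = x.shape
    y = x.data.mean(axis=(2, 3))

    def bwd(g):
        x._accumulate(np.broadcast_to(g[:, :, None, None] / (H * W), x.shape)
                      .astype(np.float32))

    return Tensor._make(y, (x,), bwd)


def bce_with_logits(x: Tensor, target: np.ndarray,
                    reduction: str = "mean") -> Tensor:
    """Numerically stable binary cross-entropy on logits."""
    t = np.asarray(target, dtype=np.float32)
    z = x.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    if reduction == "mean":
        out_data = loss.mean()
        scale = 1.0 / loss.size
    elif reduction == "sum":
        out_data = loss.sum()
        scale = 1.0
    else:
        raise ValueError(reduction)

    def bwd(g):
        x._accumulate(g * scale * (_sigmoid(z) - t))

    return Tensor._make(out_data, (x,), bwd)
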