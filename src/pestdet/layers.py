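"""Neural-network building blocks for the detector.

A light ``Module`` system over :mod:`pestdet.autograd`: parameter
registration, train/eval mode, state dictionaries for checkpointing,
and the composite blocks the architecture is assembled from —
Conv/BN/activation units, CSP bottlenecks carrying the selective-kernel
attention layer, the C3 cross-stage-partial block, spatial pyramid
pooling, and the Focus stem.

Layer-count convention (used by the complexity report): every
Conv/BN-act unit, bottleneck, pooling layer, upsample, concatenation,
space-to-depth and per-scale head counts once; a bottleneck counts once
as a whole regardless of what it contains.  Each block exposes this
through ``layer_units``.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Minimal container with parameter registration and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def register_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(value, dtype=np.float32), requires_grad=True)
        self._params[name] = t
        object.__setattr__(self, name, t)
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=np.float32)
        self._buffers[name] = arr
        object.__setattr__(self, name, arr)
        return arr

    def modules(self):
        yield self
        for child in self._children.values():
            yield from child.modules()

    def parameters(self):
        for m in self.modules():
            yield from m._params.values()

    def named_state(self, prefix: str = ""):
        for k, v in self._params.items():
            yield prefix + k, v.data
        for k, v in self._buffers.items():
            yield prefix + k, v
        for name, child in self._children.items():
            yield from child.named_state(prefix + name + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_state()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_state())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)[:5]} ...")
        for k, dst in own.items():
            src = np.asarray(state[k], dtype=np.float32)
            if src.shape != dst.shape:
                raise ValueError(f"shape mismatch for {k}: {src.shape} vs {dst.shape}")
            dst[...] = src

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def freeze_bn_stats(self):
        """Pin every batch-norm layer to its running statistics (see
        :class:`BatchNorm`)."""
        for m in self.modules():
            if isinstance(m, BatchNorm):
                m.frozen_stats = True
        return self

    def num_params(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # complexity-report hook; composites override
    layer_units: int = 0


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Conv2d(Module):
    layer_units = 1

    def __init__(self, cin: int, cout: int, k: int = 1, stride: int = 1,
                 padding: int | None = None, bias: bool = True, *,
                 rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.register_param("weight", _kaiming(rng, (cout, cin, k, k), cin * k * k))
        self.has_bias = bias
        if bias:
            self.register_param("bias", np.zeros(cout, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias if self.has_bias else None,
                         stride=self.stride, padding=self.padding)

    __call__ = forward


class BatchNorm(Module):
    """Batch normalisation with optional statistic freezing.

    With ``frozen_stats`` set the layer normalises by its running
    statistics even in training mode (gamma/beta keep their gradients and
    the running estimates stop updating).  With ``per_sample`` set the
    layer instead normalises every sample by its own spatial statistics in
    both modes (instance-style) — batch-size independent and free of any
    train/eval statistics gap, the configuration used when training with
    very small batches, where batch statistics are image-specific.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.frozen_stats = False
        self.per_sample = False  # instance-style statistics (4-D input only)
        self.register_param("gamma", np.ones(c, dtype=np.float32))
        self.register_param("beta", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return ag.batch_norm(x, self.gamma, self.beta, self.running_mean,
                             self.running_var,
                             self.training and not self.frozen_stats,
                             self.momentum, self.eps,
                             per_sample=self.per_sample)

    __call__ = forward


class Linear(Module):
    def __init__(self, cin: int, cout: int, bias: bool = True, *,
                 rng: np.random.Generator):
        super().__init__()
        self.register_param("weight", _kaiming(rng, (cout, cin), cin))
        self.has_bias = bias
        if bias:
            self.register_param("bias", np.zeros(cout, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return ag.linear(x, self.weight, self.bias if self.has_bias else None)

    __call__ = forward


def _activate(x: Tensor, act: str) -> Tensor:
    if act == "silu":
        return x.silu()
    if act == "relu":
        return x.relu()
    if act == "identity":
        return x
    raise ValueError(f"unknown activation {act!r}")


class ConvBNAct(Module):
    """Conv -> BatchNorm -> activation: the basic 'convolution' unit."""

    layer_units = 1

    def __init__(self, cin: int, cout: int, k: int = 1, stride: int = 1,
                 act: str = "silu", *, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, bias=False, rng=rng)
        self.bn = BatchNorm(cout)
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        return _activate(self.bn(self.conv(x)), self.act)

    __call__ = forward


class SKAttention(Module):
    """Selective-kernel channel attention: split / fuse / scale.

    Split runs 3x3 and 5x5 convolution branches (U1, U2) and adds them;
    fuse compresses U = U1 + U2 with global average pooling and pushes it
    through FC -> BN -> ReLU -> FC -> sigmoid to get one channel weight
    vector a in (0,1)^C; scale multiplies both branches by the same vector,
    so the output is V = U1*a + U2*a = (U1 + U2)*a.  A classic two-branch
    softmax variant (separate weights per branch, summing to 1 across
    branches) is available behind ``classic_softmax``.
    """

    def __init__(self, c: int, reduction: int = 16,
                 classic_softmax: bool = False, *, rng: np.random.Generator):
        super().__init__()
        self.c = c
        self.d = max(c // reduction, 8)
        self.classic_softmax = classic_softmax
        self.conv3 = Conv2d(c, c, 3, 1, bias=False, rng=rng)
        self.conv5 = Conv2d(c, c, 5, 1, bias=False, rng=rng)
        self.fc1 = Linear(c, self.d, rng=rng)
        self.bn = BatchNorm(self.d)
        self.fc2 = Linear(self.d, 2 * c if classic_softmax else c, rng=rng)

    def split(self, x: Tensor) -> tuple[Tensor, Tensor]:
        return self.conv3(x), self.conv5(x)

    def fuse(self, s: Tensor) -> Tensor:
        """Channel descriptor (B, C) -> channel weights."""
        h = self.fc1(s)
        # batch statistics need more than one descriptor; otherwise fall
        # back to the running estimates
        use_batch = (self.training and not self.bn.frozen_stats
                     and h.shape[0] > 1)
        h = ag.batch_norm(h, self.bn.gamma, self.bn.beta, self.bn.running_mean,
                          self.bn.running_var, use_batch,
                          self.bn.momentum, self.bn.eps)
        z = self.fc2(h.relu())
        if not self.classic_softmax:
            # keep weights strictly inside (0, 1): float32 sigmoid saturates
            return z.sigmoid().clamp(1e-6, 1.0 - 1e-6)
        # softmax across the two branch slots per channel
        z1 = z[:, :self.c]
        z2 = z[:, self.c:]
        m = ag.maximum(z1, z2)
        e1 = (z1 - m).exp()
        e2 = (z2 - m).exp()
        tot = e1 + e2
        return ag.concat([e1 / tot, e2 / tot], axis=1)

    def forward(self, x: Tensor) -> Tensor:
        u1, u2 = self.split(x)
        u = u1 + u2
        a = self.fuse(ag.global_avg_pool(u))
        if not self.classic_softmax:
            aw = a.reshape(a.shape[0], self.c, 1, 1)
            return u1 * aw + u2 * aw
        a1 = a[:, :self.c].reshape(a.shape[0], self.c, 1, 1)
        a2 = a[:, self.c:].reshape(a.shape[0], self.c, 1, 1)
        return u1 * a1 + u2 * a2

    __call__ = forward


class Bottleneck(Module):
    """CSP residual bottleneck: 1x1 conv, 3x3 conv, optional SK attention,
    residual add when the shape allows.  Counts once under the layer
    convention."""

    layer_units = 1

    def __init__(self, cin: int, cout: int, shortcut: bool = True,
                 use_sk: bool = False, sk_reduction: int = 16, *,
                 rng: np.random.Generator):
        super().__init__()
        ch = cout // 2
        self.cv1 = ConvBNAct(cin, ch, 1, rng=rng)
        self.cv2 = ConvBNAct(ch, cout, 3, rng=rng)
        self.sk = SKAttention(cout, sk_reduction, rng=rng) if use_sk else None
        self.add = shortcut and cin == cout

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        if self.sk is not None:
            y = self.sk(y)
        return x + y if self.add else y

    __call__ = forward


class C3(Module):
    """Cross-stage-partial block: the input is split through two 1x1
    branches, one carries n bottlenecks, and the halves are concatenated
    and fused — 'a richer gradient combination with a reduced number of
    calculations'."""

    def __init__(self, cin: int, cout: int, n: int = 1, shortcut: bool = True,
                 use_sk: bool = False, *, rng: np.random.Generator):
        super().__init__()
        ch = cout // 2
        self.cv1 = ConvBNAct(cin, ch, 1, rng=rng)
        self.cv2 = ConvBNAct(cin, ch, 1, rng=rng)
        self.cv3 = ConvBNAct(2 * ch, cout, 1, rng=rng)
        self.n = n
        for i in range(n):
            setattr(self, f"m{i}", Bottleneck(ch, ch, shortcut, use_sk, rng=rng))

    @property
    def layer_units(self) -> int:
        return 3 + self.n

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        for i in range(self.n):
            y = getattr(self, f"m{i}")(y)
        return self.cv3(ag.concat([y, self.cv2(x)], axis=1))

    __call__ = forward


class SPP(Module):
    """Spatial pyramid pooling: the identity branch plus three max-pool
    receptive fields, concatenated along channels and fused ('fusing the
    acquired results from channel dimension using four pooling layers')."""

    def __init__(self, cin: int, cout: int, kernels=(5, 9, 13), *,
                 rng: np.random.Generator):
        super().__init__()
        ch = cin // 2
        self.kernels = tuple(kernels)
        self.cv1 = ConvBNAct(cin, ch, 1, rng=rng)
        self.cv2 = ConvBNAct(ch * (len(kernels) + 1), cout, 1, rng=rng)

    # 2 conv units + 3 pools + 1 concat
    @property
    def layer_units(self) -> int:
        return 2 + len(self.kernels) + 1

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        pools = [y] + [ag.max_pool2d(y, k, 1) for k in self.kernels]
        return self.cv2(ag.concat(pools, axis=1))

    __call__ = forward


class Focus(Module):
    """Stem: lossless 2x2 space-to-depth (3 -> 12 channels, spatial side
    halved) followed by one conv unit."""

    layer_units = 2  # space-to-depth + conv unit

    def __init__(self, cin: int, cout: int, k: int = 3, *,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = ConvBNAct(4 * cin, cout, k, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(ag.space_to_depth(x))

    __call__ = forward
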