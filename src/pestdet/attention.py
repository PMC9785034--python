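"""Functional surface of the modified selective-kernel attention block.

The block (see :class:`pestdet.layers.SKAttention`) follows the
split / fuse / scale scheme:

* **split** — two convolution branches with 3x3 and 5x5 kernels give
  ``U1`` and ``U2``; their sum is the fused map ``U``;
* **fuse** — global average pooling compresses ``U`` to one descriptor
  per channel, and two fully connected layers with batch normalisation,
  ReLU and a final sigmoid turn it into a channel-weight vector
  ``a`` with every component strictly inside (0, 1);
* **scale** — both branches are reweighted by the *same* vector, so the
  block output is ``V = U1*a + U2*a = (U1 + U2)*a``.

The functions here operate on plain feature maps (``C x H x W`` or
``B x C x H x W`` arrays) and delegate to an :class:`SKAttention`
parameter block, so they can be tested against brute-force oracles
without touching the rest of the network.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import SKAttention


def _as_batched_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        arr = x.data
    else:
        arr = np.asarray(x, dtype=np.float32)
    if not np.isfinite(arr).all():
        raise ValueError("feature map contains non-finite values")
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    if arr.ndim != 4:
        raise ValueError(f"expected C x H x W or B x C x H x W, got {arr.shape}")
    return Tensor(arr), squeeze


def sk_split(x, params: SKAttention) -> tuple[np.ndarray, np.ndarray]:
    """Run the 3x3 and 5x5 branches; returns ``(U1, U2)``."""
    t, squeeze = _as_batched_tensor(x)
    if t.shape[1] != params.c:
        raise ValueError(f"channel mismatch: map has {t.shape[1]}, "
                         f"block expects {params.c}")
    with ag.no_grad():
        u1, u2 = params.split(t)
    if squeeze:
        return u1.data[0], u2.data[0]
    return u1.data, u2.data


def global_average_pool(u) -> np.ndarray:
    """Per-channel spatial mean: s_c = (1 / (W*H)) * sum_ij U_c(i, j)."""
    arr = u.data if isinstance(u, Tensor) else np.asarray(u, dtype=np.float32)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    if arr.shape[2] == 0 or arr.shape[3] == 0:
        raise ValueError("empty feature map")
    s = arr.mean(axis=(2, 3))
    return s[0] if squeeze else s


def fuse_fc(s, params: SKAttention) -> np.ndarray:
    """Channel descriptor -> channel weights a = sigmoid(FC2(ReLU(BN(FC1(s))))).

    Every component lies strictly in (0, 1) for finite input.
    """
    arr = np.asarray(s, dtype=np.float32)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite channel descriptor")
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None]
    if arr.shape[1] != params.c:
        raise ValueError(f"descriptor length {arr.shape[1]} != channels {params.c}")
    with ag.no_grad():
        a = params.fuse(Tensor(arr))
    return a.data[0] if squeeze else a.data


def sk_forward(x, params: SKAttention) -> np.ndarray:
    """Full block: V = U1*a + U2*a, with a shared channel weight vector."""
    t, squeeze = _as_batched_tensor(x)
    if t.shape[1] != params.c:
        raise ValueError(f"channel mismatch: map has {t.shape[1]}, "
                         f"block expects {params.c}")
    with ag.no_grad():
        v = params(t)
    return v.data[0] if squeeze else v.data
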