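"""The single-stage detector: Focus stem, extended CSP backbone with
selective-kernel attention, SPP, a PANet neck extended down to stride 4,
and four detection heads.

The default (proposed) configuration thickens the shallow cross-stage-
partial stages to the depth of the deeper ones (repeats 3,3,3,3), embeds
an SK attention layer in every backbone bottleneck, and adds a stride-4
(P2) branch to the neck so the smallest objects are predicted on a
128 x 128 grid at the 512 working size.  The unmodified small baseline
(repeats 1,3,3,1, no SK, strides 8/16/32) is kept for the layer-count
comparison.

Channel widths of the default spec are calibrated so the analytic
complexity report (multiply-accumulate counted as two FLOPs, 512 x 512
input) lands at 4.8 GFLOPs; see ``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .boxes import Detection, iou_xyxy, iou_wh
from .layers import (C3, SPP, Conv2d, ConvBNAct, Focus, Module)


# -- model specification -------------------------------------------------------

#: anchor table (pixel w x h, 3 per scale, strides 4/8/16/32 at 512 input)
DEFAULT_ANCHORS_P2 = (((6, 8), (12, 10), (10, 18)),
                      ((16, 24), (31, 21), (24, 40)),
                      ((44, 36), (36, 64), (68, 56)),
                      ((80, 100), (140, 120), (220, 210)))
DEFAULT_ANCHORS_P3 = DEFAULT_ANCHORS_P2[1:]

#: calibrated stage widths (c1..c5) of the default spec — see module docstring
PROPOSED_WIDTHS = (14, 28, 56, 112, 224)


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyper-parameters of one detector variant."""

    name: str = "proposed"
    input_size: int = 512
    num_classes: int = 5
    widths: tuple[int, ...] = PROPOSED_WIDTHS
    repeats: tuple[int, ...] = (3, 3, 3, 3)
    strides: tuple[int, ...] = (4, 8, 16, 32)
    use_sk: bool = True
    sk_reduction: int = 16
    activation: str = "silu"
    spp_kernels: tuple[int, ...] = (5, 9, 13)
    anchors: tuple = DEFAULT_ANCHORS_P2
    #: "running": classic batch norm (batch stats in training, running at
    #: inference).  "instance": per-sample spatial statistics in both modes,
    #: the small-batch CPU training configuration.
    norm_stats: str = "running"

    def __post_init__(self):
        if self.input_size % 32:
            raise ValueError(f"input_size must be divisible by 32: {self.input_size}")
        if len(self.widths) != 5 or any(c <= 0 for c in self.widths):
            raise ValueError(f"need 5 positive stage widths, got {self.widths}")
        if len(self.repeats) != 4 or any(n < 1 for n in self.repeats):
            raise ValueError(f"need 4 positive repeat counts, got {self.repeats}")
        if len(self.strides) not in (3, 4):
            raise ValueError(f"need 3 or 4 strides, got {self.strides}")
        if len(self.anchors) != len(self.strides) or any(
                len(per_scale) != 3 for per_scale in self.anchors):
            raise ValueError("need 3 anchors per detection scale")
        if self.norm_stats not in ("running", "instance"):
            raise ValueError(f"unknown norm_stats mode {self.norm_stats!r}")

    @property
    def num_scales(self) -> int:
        return len(self.strides)

    def with_anchors(self, anchors) -> "ModelSpec":
        anchors = tuple(tuple((float(w), float(h)) for w, h in per_scale)
                        for per_scale in anchors)
        return dataclasses.replace(self, anchors=anchors)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        for key in ("widths", "repeats", "strides", "spp_kernels"):
            d[key] = tuple(d[key])
        d["anchors"] = tuple(tuple(tuple(a) for a in per_scale)
                             for per_scale in d["anchors"])
        return cls(**d)


def proposed_spec(num_classes: int = 5, input_size: int = 512) -> ModelSpec:
    """The modified detector: thickened shallow CSP, SK attention, P2 head."""
    return ModelSpec(name="proposed", input_size=input_size,
                     num_classes=num_classes)


def small_baseline_spec(num_classes: int = 5, input_size: int = 512) -> ModelSpec:
    """The unmodified small baseline at the same widths: repeats 1,3,3,1,
    no SK attention, three scales (strides 8/16/32)."""
    return ModelSpec(name="small_baseline", input_size=input_size,
                     num_classes=num_classes, repeats=(1, 3, 3, 1),
                     strides=(8, 16, 32), use_sk=False,
                     anchors=DEFAULT_ANCHORS_P3)


# -- marker modules so upsample/concat enter the layer count -------------------

class Upsample(Module):
    layer_units = 1

    def forward(self, x: Tensor) -> Tensor:
        return ag.upsample_nearest2x(x)

    __call__ = forward


class Concat(Module):
    layer_units = 1

    def forward(self, xs) -> Tensor:
        return ag.concat(xs, axis=1)

    __call__ = forward


# -- the network ----------------------------------------------------------------

class Detector(Module):
    """Backbone + neck + heads assembled from a :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, *, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        c1, c2, c3, c4, c5 = spec.widths
        n1, n2, n3, n4 = spec.repeats
        sk = spec.use_sk
        act = spec.activation
        kw = dict(rng=rng)

        def c3_block(cin, cout, n, shortcut=True, use_sk=False):
            blk = C3(cin, cout, n, shortcut, use_sk, rng=rng)
            for m in blk.modules():
                if isinstance(m, ConvBNAct):
                    m.act = act
            return blk

        # backbone
        self.focus = Focus(3, c1, **kw)
        self.conv1 = ConvBNAct(c1, c2, 3, 2, act, **kw)
        self.csp1 = c3_block(c2, c2, n1, use_sk=sk)
        self.conv2 = ConvBNAct(c2, c3, 3, 2, act, **kw)
        self.csp2 = c3_block(c3, c3, n2, use_sk=sk)
        self.conv3 = ConvBNAct(c3, c4, 3, 2, act, **kw)
        self.csp3 = c3_block(c4, c4, n3, use_sk=sk)
        self.conv4 = ConvBNAct(c4, c5, 3, 2, act, **kw)
        self.spp = SPP(c5, c5, spec.spp_kernels, **kw)
        self.csp4 = c3_block(c5, c5, n4, shortcut=False, use_sk=sk)

        # neck: top-down then bottom-up; the P2 branch only on 4-scale specs
        self.p2_branch = spec.num_scales == 4
        self.red5 = ConvBNAct(c5, c4, 1, 1, act, **kw)
        self.up5 = Upsample()
        self.cat5 = Concat()
        self.td4 = c3_block(2 * c4, c4, 1, shortcut=False)
        self.red4 = ConvBNAct(c4, c3, 1, 1, act, **kw)
        self.up4 = Upsample()
        self.cat4 = Concat()
        self.td3 = c3_block(2 * c3, c3, 1, shortcut=False)
        if self.p2_branch:
            self.red3 = ConvBNAct(c3, c2, 1, 1, act, **kw)
            self.up3 = Upsample()
            self.cat3 = Concat()
            self.td2 = c3_block(2 * c2, c2, 1, shortcut=False)
            self.down2 = ConvBNAct(c2, c2, 3, 2, act, **kw)
            self.cat_bu3 = Concat()
            self.bu3 = c3_block(2 * c2, c3, 1, shortcut=False)
        self.down3 = ConvBNAct(c3, c3, 3, 2, act, **kw)
        self.cat_bu4 = Concat()
        self.bu4 = c3_block(2 * c3, c4, 1, shortcut=False)
        self.down4 = ConvBNAct(c4, c4, 3, 2, act, **kw)
        self.cat_bu5 = Concat()
        self.bu5 = c3_block(2 * c4, c5, 1, shortcut=False)

        head_widths = (c2, c3, c4, c5) if self.p2_branch else (c3, c4, c5)
        out_ch = 3 * (5 + spec.num_classes)
        self.heads = []
        for i, ch in enumerate(head_widths):
            head = Conv2d(ch, out_ch, 1, bias=True, **kw)
            setattr(self, f"head{i}", head)
            self.heads.append(head)
        self._init_head_biases()
        if spec.norm_stats == "instance":
            from .layers import BatchNorm

            for m in self.modules():
                if isinstance(m, BatchNorm):
                    m.per_sample = True

    def _init_head_biases(self):
        """Prior biases: low objectness (about 8 objects per scale image),
        near-uniform class logits — stabilises early training."""
        k = self.spec.num_classes
        for head, stride in zip(self.heads, self.spec.strides):
            b = head.bias.data.reshape(3, 5 + k)
            b[:, 4] += np.log(8.0 / (self.spec.input_size / stride) ** 2)
            b[:, 5:] += np.log(0.6 / (k - 0.99)) if k > 1 else 0.0

    # -- forward ---------------------------------------------------------------
    def forward_tensors(self, x: Tensor) -> list[Tensor]:
        """Raw head outputs, finest scale first, each (B, 3*(5+K), H, W)."""
        x = self.focus(x)
        p2f = self.csp1(self.conv1(x))
        p3f = self.csp2(self.conv2(p2f))
        p4f = self.csp3(self.conv3(p3f))
        p5f = self.csp4(self.spp(self.conv4(p4f)))

        r5 = self.red5(p5f)
        t4 = self.td4(self.cat5([self.up5(r5), p4f]))
        r4 = self.red4(t4)
        t3 = self.td3(self.cat4([self.up4(r4), p3f]))
        if self.p2_branch:
            r3 = self.red3(t3)
            t2 = self.td2(self.cat3([self.up3(r3), p2f]))
            out2 = t2
            b3 = self.bu3(self.cat_bu3([self.down2(t2), r3]))
        else:
            b3 = t3
        b4 = self.bu4(self.cat_bu4([self.down3(b3), r4]))
        b5 = self.bu5(self.cat_bu5([self.down4(b4), r5]))

        feats = ([out2, b3, b4, b5] if self.p2_branch else [b3, b4, b5])
        return [head(f) for head, f in zip(self.heads, feats)]

    __call__ = forward_tensors

    def raw_tensors(self, x: Tensor) -> list[Tensor]:
        """Head outputs reshaped to (B, 3, H, W, 5+K), autograd-connected."""
        k = self.spec.num_classes
        outs = []
        for t in self.forward_tensors(x):
            b, _, h, w = t.shape
            outs.append(t.reshape(b, 3, 5 + k, h, w).moveaxis(2, 4))
        return outs

    # -- layer counting ---------------------------------------------------------
    def blocks(self) -> list[Module]:
        names = ["focus", "conv1", "csp1", "conv2", "csp2", "conv3", "csp3",
                 "conv4", "spp", "csp4",
                 "red5", "up5", "cat5", "td4", "red4", "up4", "cat4", "td3"]
        if self.p2_branch:
            names += ["red3", "up3", "cat3", "td2", "down2", "cat_bu3", "bu3"]
        names += ["down3", "cat_bu4", "bu4", "down4", "cat_bu5", "bu5"]
        return [getattr(self, n) for n in names] + list(self.heads)

    def layer_count(self) -> int:
        """Module-summary layer count: every conv/BN-act unit, bottleneck,
        pool, upsample, concat, space-to-depth and per-scale head counts
        once; a bottleneck counts once as a whole."""
        return int(sum(b.layer_units for b in self.blocks()))


def build_model(spec: ModelSpec, seed: int = 0) -> Detector:
    """Construct a detector with seeded parameter initialisation."""
    return Detector(spec, rng=np.random.default_rng([seed, 0x5EED]))


def focus_transform(image: np.ndarray) -> np.ndarray:
    """Lossless 2x2 space-to-depth on an H x W x 3 image -> 12 x H/2 x W/2.

    Each output channel group is one of the four pixel phases; the map is
    a permutation of the input values.
    """
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got {arr.shape}")
    if arr.shape[0] % 2 or arr.shape[1] % 2:
        raise ValueError("image height and width must be even")
    chw = np.moveaxis(arr, 2, 0)[None]
    with ag.no_grad():
        out = ag.space_to_depth(Tensor(chw))
    return out.data[0]


def focus_inverse(fmap: np.ndarray) -> np.ndarray:
    """Reassemble the four phases back into the H x W x 3 image."""
    x = ag.depth_to_space(np.asarray(fmap, dtype=np.float32)[None])[0]
    return np.moveaxis(x, 0, 2)


def forward(model: Detector, batch: np.ndarray) -> list[np.ndarray]:
    """Inference pass: B x 3 x S x S float batch -> per-scale raw
    predictions (B, 3, H_s, W_s, 5+K), finest grid first."""
    batch = np.asarray(batch, dtype=np.float32)
    if batch.ndim != 4 or batch.shape[1] != 3:
        raise ValueError(f"expected B x 3 x H x W batch, got {batch.shape}")
    if batch.shape[2] % 32 or batch.shape[3] % 32:
        raise ValueError("input size must be divisible by 32")
    with ag.no_grad():
        outs = model.raw_tensors(Tensor(batch))
    return [t.data for t in outs]


def preprocess(image_u8: np.ndarray) -> np.ndarray:
    """uint8 H x W x 3 -> normalized 3 x H x W float32 in [0, 1]."""
    return np.moveaxis(np.asarray(image_u8, dtype=np.float32) / 255.0, 2, 0)


# -- decode / NMS ----------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def decode(raw: list[np.ndarray], spec: ModelSpec,
           conf_thresh: float = 0.25) -> list[Detection]:
    """Raw single-image predictions -> pixel-space detections.

    Per anchor ``a`` and cell ``(i, j)``: center = (2*sigmoid(txy) - 0.5 +
    (j, i)) * stride, size = (2*sigmoid(twh))^2 * anchor, score =
    sigmoid(obj) * sigmoid(cls); candidates below ``conf_thresh`` are
    dropped.  One detection may be emitted per class passing the threshold.
    """
    if not 0.0 <= conf_thresh <= 1.0:
        raise ValueError(f"conf_thresh outside [0,1]: {conf_thresh}")
    dets: list[Detection] = []
    for arr, stride, anchors in zip(raw, spec.strides, spec.anchors):
        arr = np.asarray(arr)
        if arr.ndim != 4:
            raise ValueError("decode expects single-image raw predictions "
                             "(3, H, W, 5+K) per scale")
        _, h, w, _ = arr.shape
        s = _sigmoid(arr)
        jj, ii = np.meshgrid(np.arange(w), np.arange(h))  # jj: x, ii: y
        anc = np.asarray(anchors, dtype=np.float64)  # (3, 2)
        cx = (2 * s[..., 0] - 0.5 + jj[None]) * stride
        cy = (2 * s[..., 1] - 0.5 + ii[None]) * stride
        bw = (2 * s[..., 2]) ** 2 * anc[:, 0, None, None]
        bh = (2 * s[..., 3]) ** 2 * anc[:, 1, None, None]
        scores = s[..., 4:5] * s[..., 5:]  # (3, H, W, K)
        keep = np.argwhere(scores >= conf_thresh)
        for a, i, j, c in keep:
            x1 = cx[a, i, j] - bw[a, i, j] / 2
            y1 = cy[a, i, j] - bh[a, i, j] / 2
            x2 = x1 + bw[a, i, j]
            y2 = y1 + bh[a, i, j]
            if x2 <= x1 or y2 <= y1:  # sigmoid underflow can zero the size
                continue
            dets.append(Detection(int(c), float(scores[a, i, j, c]),
                                  (float(x1), float(y1), float(x2), float(y2))))
    return dets


def nms(dets: list[Detection], iou_thresh: float = 0.45) -> list[Detection]:
    """Greedy class-wise non-maximum suppression, score descending; among
    survivors no same-class pair overlaps with IoU above the threshold.
    Equal scores are broken by input order (stable)."""
    out: list[Detection] = []
    by_class: dict[int, list[Detection]] = {}
    for d in dets:
        by_class.setdefault(d.class_id, []).append(d)
    for cls in sorted(by_class):
        cand = sorted(by_class[cls], key=lambda d: -d.score)
        boxes = np.array([d.box for d in cand], dtype=np.float64)
        alive = np.ones(len(cand), dtype=bool)
        for i in range(len(cand)):
            if not alive[i]:
                continue
            out.append(cand[i])
            if i + 1 < len(cand):
                ious = iou_xyxy(boxes[i][None], boxes[i + 1:])[0]
                alive[i + 1:] &= ious <= iou_thresh
    return out


def detect_image(model: Detector, image_u8: np.ndarray,
                 conf_thresh: float = 0.25, iou_thresh: float = 0.45,
                 input_size: int | None = None) -> list[Detection]:
    """Letterbox -> forward -> decode -> NMS -> map back to original pixels."""
    from .yolo_io import letterbox

    size = input_size or model.spec.input_size
    padded, tf = letterbox(image_u8, size)
    raw = forward(model, preprocess(padded)[None])
    dets = decode([r[0] for r in raw], model.spec, conf_thresh)
    dets = nms(dets, iou_thresh)
    out = []
    for d in dets:
        box = tf.invert_xyxy(np.asarray(d.box))
        w0, h0 = tf.original_size
        box = np.clip(box, [0, 0, 0, 0], [w0, h0, w0, h0])
        if box[2] > box[0] and box[3] > box[1]:
            out.append(Detection(d.class_id, d.score, tuple(box)))
    return out


# -- anchor computation -----------------------------------------------------------

def compute_anchors(wh: np.ndarray, num_anchors: int = 12, seed: int = 0,
                    restarts: int = 8, iters: int = 60):
    """k-means on pixel (w, h) pairs under the 1 - IoU distance.

    Returns anchors grouped three per scale in ascending-area triples.
    Falls back to the default anchor table (with a warning) when fewer
    boxes than anchors are available.
    """
    wh = np.atleast_2d(np.asarray(wh, dtype=np.float64))
    if wh.shape[0] < num_anchors:
        warnings.warn(f"only {wh.shape[0]} boxes for {num_anchors} anchors; "
                      "falling back to the default anchor table")
        table = DEFAULT_ANCHORS_P2 if num_anchors == 12 else DEFAULT_ANCHORS_P3
        return np.asarray(table, dtype=np.float64)
    rng = np.random.default_rng(seed)
    best, best_cost = None, np.inf
    for _ in range(restarts):
        centers = _kmeanspp_init(wh, num_anchors, rng)
        for _ in range(iters):
            dist = 1.0 - iou_wh(wh, centers)  # (N, k)
            assign = dist.argmin(axis=1)
            new = centers.copy()
            for k in range(num_anchors):
                members = wh[assign == k]
                if len(members):
                    new[k] = members.mean(axis=0)
                else:  # re-seed empty cluster at the worst-covered box
                    new[k] = wh[dist.min(axis=1).argmax()]
            if np.allclose(new, centers, rtol=1e-6, atol=1e-8):
                centers = new
                break
            centers = new
        cost = (1.0 - iou_wh(wh, centers)).min(axis=1).mean()
        if cost < best_cost:
            best, best_cost = centers, cost
    order = np.argsort(best[:, 0] * best[:, 1], kind="stable")
    anchors = best[order]
    return anchors.reshape(num_anchors // 3, 3, 2)


def _kmeanspp_init(wh: np.ndarray, k: int, rng: np.random.Generator):
    centers = [wh[rng.integers(len(wh))]]
    for _ in range(k - 1):
        d = (1.0 - iou_wh(wh, np.array(centers))).min(axis=1)
        p = d / d.sum() if d.sum() > 0 else None
        centers.append(wh[rng.choice(len(wh), p=p)])
    return np.array(centers, dtype=np.float64)


def anchors_from_labels(samples, input_size: int, num_scales: int = 4):
    """Anchor table from a labeled sample list (pixel sizes at input_size)."""
    wh = np.array([[b.w * input_size, b.h * input_size]
                   for s in samples for b in s.boxes], dtype=np.float64)
    return compute_anchors(wh, num_anchors=3 * num_scales)


# -- checkpoints ------------------------------------------------------------------

def save_checkpoint(path: str | Path, model: Detector):
    """Weights + spec in one .npz (spec as a JSON side string)."""
    payload = {f"param:{k}": v for k, v in model.named_state()}
    payload["spec_json"] = np.frombuffer(
        json.dumps(model.spec.to_dict()).encode(), dtype=np.uint8)
    np.savez(Path(path), **payload)


def load_checkpoint(path: str | Path) -> Detector:
    with np.load(Path(path)) as z:
        spec = ModelSpec.from_dict(
            json.loads(bytes(z["spec_json"].tolist()).decode()))
        state = {k[len("param:"):]: z[k] for k in z.files if k.startswith("param:")}
    model = build_model(spec)
    model.load_state_dict(state)
    return model
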