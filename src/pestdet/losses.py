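"""Target assignment and the composite detection loss.

The per-layer loss is the sum of three terms — class loss, objectness
(confidence) loss and bounding-box regression loss — and the total is
that sum accumulated over the detection layers:

    loss = loss_class + loss_object + loss_bounding_box

Box regression uses CIoU (complete IoU): IoU minus a normalized
center-distance penalty and an aspect-ratio penalty, so the box term is
``1 - CIoU`` averaged over assigned prediction slots.  Class and
objectness terms are logistic (binary cross-entropy on logits); the
objectness target at an assigned slot is the detached CIoU of its
prediction, clamped at zero, so confidence learns to track localization
quality.

Assignment follows the anchor-ratio rule: a ground-truth box is assigned
to an anchor when ``max(w/aw, aw/w, h/ah, ah/h) < 4``, at the cell
containing its center plus the two nearest neighbor cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .boxes import NormBox
from .network import ModelSpec

_EPS = 1e-9

#: objectness balance over detection layers, finest grid first
BALANCE_4 = (4.0, 1.0, 0.4, 0.1)
BALANCE_3 = (4.0, 1.0, 0.4)

#: term gains (box, objectness, class)
DEFAULT_GAINS = {"box": 0.05, "obj": 1.0, "cls": 0.5}

ANCHOR_RATIO_THRESH = 4.0


# -- CIoU ------------------------------------------------------------------------

def ciou(box_a, box_b) -> float:
    """Complete IoU of two pixel xyxy boxes, in (-1, 1].

    CIoU = IoU - rho^2/c^2 - alpha*v, where rho is the center distance, c
    the diagonal of the smallest enclosing box, v the squared normalized
    arctan aspect-ratio gap and alpha = v / ((1 - IoU) + v).  Equals plain
    IoU for boxes sharing center and aspect ratio.  Degenerate (zero-area)
    boxes are rejected.
    """
    ax1, ay1, ax2, ay2 = (float(v) for v in box_a)
    bx1, by1, bx2, by2 = (float(v) for v in box_b)
    aw, ah = ax2 - ax1, ay2 - ay1
    bw, bh = bx2 - bx1, by2 - by1
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise ValueError("zero-area box in CIoU")
    inter = (max(0.0, min(ax2, bx2) - max(ax1, bx1))
             * max(0.0, min(ay2, by2) - max(ay1, by1)))
    union = aw * ah + bw * bh - inter
    iou = inter / (union + _EPS)
    cw = max(ax2, bx2) - min(ax1, bx1)
    ch = max(ay2, by2) - min(ay1, by1)
    c2 = cw * cw + ch * ch + _EPS
    rho2 = (((ax1 + ax2) - (bx1 + bx2)) ** 2
            + ((ay1 + ay2) - (by1 + by2)) ** 2) / 4.0
    v = (4.0 / np.pi ** 2) * (np.arctan(bw / bh) - np.arctan(aw / ah)) ** 2
    alpha = v / ((1.0 - iou) + v + _EPS)
    return float(iou - rho2 / c2 - alpha * v)


def _ciou_tensor(pred_cs: Tensor, target_cs: np.ndarray) -> Tensor:
    """Differentiable CIoU for (N, 4) center-size boxes against constants.

    ``alpha`` is treated as a constant (evaluated from current values), the
    usual stabilisation of the CIoU gradient.
    """
    t = np.asarray(target_cs, dtype=np.float32)
    px, py = pred_cs[:, 0], pred_cs[:, 1]
    pw = pred_cs[:, 2].clamp(1e-4, None)
    ph = pred_cs[:, 3].clamp(1e-4, None)
    tx, ty, tw, th = t[:, 0], t[:, 1], t[:, 2], t[:, 3]

    px1, px2 = px - pw * 0.5, px + pw * 0.5
    py1, py2 = py - ph * 0.5, py + ph * 0.5
    tx1, tx2 = tx - tw * 0.5, tx + tw * 0.5
    ty1, ty2 = ty - th * 0.5, ty + th * 0.5

    iw = (ag.minimum(px2, Tensor(tx2)) - ag.maximum(px1, Tensor(tx1))).clamp(0.0, None)
    ih = (ag.minimum(py2, Tensor(ty2)) - ag.maximum(py1, Tensor(ty1))).clamp(0.0, None)
    inter = iw * ih
    union = pw * ph + Tensor(tw * th) - inter
    iou = inter / (union + _EPS)

    cw = ag.maximum(px2, Tensor(tx2)) - ag.minimum(px1, Tensor(tx1))
    chh = ag.maximum(py2, Tensor(ty2)) - ag.minimum(py1, Tensor(ty1))
    c2 = cw * cw + chh * chh + _EPS
    rho2 = (px - Tensor(tx)) ** 2.0 + (py - Tensor(ty)) ** 2.0

    v = ((Tensor(np.arctan(tw / np.maximum(th, 1e-9))) - (pw / ph).arctan()) ** 2.0
         * (4.0 / np.pi ** 2))
    alpha = v.data / ((1.0 - iou.data) + v.data + _EPS)  # constant
    return iou - rho2 / c2 - v * Tensor(alpha)


# -- assignment ------------------------------------------------------------------

@dataclass
class ScaleAssignment:
    """Assigned prediction slots at one detection layer (parallel arrays)."""

    image: np.ndarray      # batch index per slot
    anchor: np.ndarray     # anchor index in [0, 3)
    cell_i: np.ndarray     # grid row
    cell_j: np.ndarray     # grid column
    tbox: np.ndarray       # (N, 4) target cx, cy (cell-relative + cell), w, h in grid units
    cls: np.ndarray        # class ids
    unassigned: int = 0    # labels that matched no anchor at this scale

    def __len__(self):
        return len(self.image)


@dataclass
class TargetAssignment:
    per_scale: list[ScaleAssignment] = field(default_factory=list)

    @property
    def num_unassigned_labels(self) -> int:
        """Labels that matched no anchor at any scale."""
        return self._unassigned_total

    _unassigned_total: int = 0


def assign_targets(labels: list[NormBox], spec: ModelSpec,
                   input_size: int | None = None) -> TargetAssignment:
    """Single-image assignment (batch index 0 throughout)."""
    return assign_batch([labels], spec, input_size)


def assign_batch(labels_per_image: list[list[NormBox]], spec: ModelSpec,
                 input_size: int | None = None) -> TargetAssignment:
    """Assign every label to (scale, anchor, cell) slots.

    Per scale, a label is kept for anchor ``a`` when the largest of the
    four width/height ratios is below :data:`ANCHOR_RATIO_THRESH`; it is
    then replicated to its containing cell and the two nearest neighbor
    cells (the nearer horizontal and vertical one).  Labels matching no
    anchor anywhere are counted, not raised.
    """
    size = input_size or spec.input_size
    rows = []  # (image, cls, cx, cy, w, h) normalized
    for b, labels in enumerate(labels_per_image):
        for lb in labels:
            rows.append((b, lb.class_id, lb.cx, lb.cy, lb.w, lb.h))
    data = np.asarray(rows, dtype=np.float64).reshape(-1, 6)

    out = TargetAssignment()
    assigned_any = np.zeros(len(data), dtype=bool)
    for stride, anchors in zip(spec.strides, spec.anchors):
        gw = size // stride
        anc = np.asarray(anchors, dtype=np.float64) / stride  # grid units
        if len(data) == 0:
            out.per_scale.append(ScaleAssignment(
                *(np.zeros(0, dtype=np.int64) for _ in range(4)),
                np.zeros((0, 4)), np.zeros(0, dtype=np.int64)))
            continue
        g = np.empty((len(data), 4))
        g[:, 0] = data[:, 2] * gw          # cx in grid units
        g[:, 1] = data[:, 3] * gw
        g[:, 2] = data[:, 4] * gw
        g[:, 3] = data[:, 5] * gw
        img_l, anc_l, ci_l, cj_l, tb_l, cl_l = [], [], [], [], [], []
        for a_idx in range(3):
            r = g[:, 2:4] / anc[a_idx]
            keep = np.maximum(r, 1.0 / r).max(axis=1) < ANCHOR_RATIO_THRESH
            for gi_row in np.flatnonzero(keep):
                assigned_any[gi_row] = True
                cx, cy, w, h = g[gi_row]
                gj = int(np.clip(np.floor(cx), 0, gw - 1))
                gi = int(np.clip(np.floor(cy), 0, gw - 1))
                cells = [(gi, gj)]
                fx, fy = cx - np.floor(cx), cy - np.floor(cy)
                if fx < 0.5 and cx > 1.0:
                    cells.append((gi, gj - 1))
                elif fx >= 0.5 and cx < gw - 1.0:
                    cells.append((gi, gj + 1))
                if fy < 0.5 and cy > 1.0:
                    cells.append((gi - 1, gj))
                elif fy >= 0.5 and cy < gw - 1.0:
                    cells.append((gi + 1, gj))
                for ci, cj in cells:
                    if not (0 <= ci < gw and 0 <= cj < gw):
                        continue
                    img_l.append(int(data[gi_row, 0]))
                    anc_l.append(a_idx)
                    ci_l.append(ci)
                    cj_l.append(cj)
                    tb_l.append((cx - cj, cy - ci, w, h))
                    cl_l.append(int(data[gi_row, 1]))
        out.per_scale.append(ScaleAssignment(
            np.asarray(img_l, dtype=np.int64), np.asarray(anc_l, dtype=np.int64),
            np.asarray(ci_l, dtype=np.int64), np.asarray(cj_l, dtype=np.int64),
            np.asarray(tb_l, dtype=np.float64).reshape(-1, 4),
            np.asarray(cl_l, dtype=np.int64)))
    out._unassigned_total = int((~assigned_any).sum())
    return out


# -- the composite loss -----------------------------------------------------------

@dataclass
class LossReport:
    """Weighted components and their exact sum."""

    loss_box: float
    loss_object: float
    loss_class: float
    total: float
    total_tensor: Tensor | None = None

    def __post_init__(self):
        if np.isfinite(self.total):  # divergence is reported, not asserted
            assert self.total == self.loss_box + self.loss_object + self.loss_class


def compute_loss(raw: list[Tensor], assignment: TargetAssignment,
                 spec: ModelSpec, gains: dict | None = None,
                 input_size: int | None = None) -> LossReport:
    """Composite loss over the detection layers.

    ``raw`` holds per-scale head outputs shaped (B, 3, H, W, 5+K) with
    autograd attached (see :meth:`Detector.raw_tensors`).  The box term is
    ``mean(1 - CIoU)`` over assigned slots; the class term is logistic
    cross-entropy over the K class logits at assigned slots; the
    objectness term is logistic cross-entropy over every slot, with the
    assigned slots' target set to the detached, zero-clamped CIoU, and is
    balance-weighted per layer.  With no assigned slots the box and class
    terms are zero while objectness is still computed.
    """
    gains = {**DEFAULT_GAINS, **(gains or {})}
    size = input_size or spec.input_size
    balance = BALANCE_4 if spec.num_scales == 4 else BALANCE_3
    k = spec.num_classes

    lbox = Tensor(np.float32(0.0))
    lcls = Tensor(np.float32(0.0))
    lobj = Tensor(np.float32(0.0))
    for s_idx, (t, sa, stride, anchors) in enumerate(
            zip(raw, assignment.per_scale, spec.strides, spec.anchors)):
        obj_target = np.zeros(t.shape[:4], dtype=np.float32)
        if len(sa):
            slot = (sa.image, sa.anchor, sa.cell_i, sa.cell_j)
            pred = t[slot]  # (N, 5+K)
            anc = (np.asarray(anchors, dtype=np.float32) / stride)[sa.anchor]
            pxy = pred[:, 0:2].sigmoid() * 2.0 - 0.5
            pwh = (pred[:, 2:4].sigmoid() * 2.0) ** 2.0 * Tensor(anc)
            pbox = ag.concat([pxy, pwh], axis=1)
            ci = _ciou_tensor(pbox, sa.tbox)
            lbox = lbox + (1.0 - ci).mean()
            obj_target[slot] = np.clip(ci.data, 0.0, None)
            if k > 1:
                cls_target = np.zeros((len(sa), k), dtype=np.float32)
                cls_target[np.arange(len(sa)), sa.cls] = 1.0
                lcls = lcls + ag.bce_with_logits(pred[:, 5:], cls_target)
        lobj = lobj + balance[s_idx] * ag.bce_with_logits(t[..., 4], obj_target)

    lbox = gains["box"] * lbox
    lcls = gains["cls"] * lcls
    lobj = gains["obj"] * lobj
    total = lbox + lobj + lcls
    box_f, obj_f, cls_f = lbox.item(), lobj.item(), lcls.item()
    return LossReport(loss_box=box_f, loss_object=obj_f, loss_class=cls_f,
                      total=box_f + obj_f + cls_f, total_tensor=total)
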