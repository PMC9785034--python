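"""Detection evaluation: precision, recall, average precision, mAP and
the background-aware confusion matrix.

Definitions: P = TP / (TP + FP), R = TP / (TP + FN); AP is the area under
the monotone-envelope precision-recall curve built by descending score
(all-point interpolation; the 11-point variant is available); mAP is the
unweighted mean of per-class APs.  Matching is greedy within class by
descending score: a detection is a true positive iff its IoU with some
still-unmatched same-class ground truth reaches the threshold.  The
confusion matrix carries one extra background category absorbing
undetected ground truths (background row) and unmatched detections
(background column); columns are normalized to sum to one where nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxes import Detection, iou_xyxy

GroundTruth = tuple[int, np.ndarray]  # (class_id, pixel xyxy)


@dataclass
class MatchRecord:
    """Per-detection (score, class, TP flag) plus per-class GT counts."""

    scores: np.ndarray = field(default_factory=lambda: np.zeros(0))
    classes: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    tp: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    gt_per_class: dict[int, int] = field(default_factory=dict)

    def merge(self, other: "MatchRecord") -> "MatchRecord":
        out = MatchRecord(
            np.concatenate([self.scores, other.scores]),
            np.concatenate([self.classes, other.classes]),
            np.concatenate([self.tp, other.tp]),
            dict(self.gt_per_class))
        for c, n in other.gt_per_class.items():
            out.gt_per_class[c] = out.gt_per_class.get(c, 0) + n
        return out

    def counts(self, class_id: int | None = None) -> tuple[int, int, int]:
        """(TP, FP, FN) overall or for one class."""
        sel = slice(None) if class_id is None else (self.classes == class_id)
        tp = int(self.tp[sel].sum())
        fp = int((~self.tp[sel]).sum())
        n_gt = (sum(self.gt_per_class.values()) if class_id is None
                else self.gt_per_class.get(class_id, 0))
        return tp, fp, n_gt - tp


def match_detections(dets: list[Detection], gts: list[GroundTruth],
                     iou_thresh: float = 0.5) -> MatchRecord:
    """Greedy score-descending matching within class for one image.

    Each ground truth is matched at most once; a detection takes the
    highest-IoU still-free ground truth of its class if that IoU reaches
    the threshold, else it is a false positive.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    gt_boxes = np.array([g[1] for g in gts], dtype=np.float64).reshape(-1, 4)
    gt_cls = np.array([g[0] for g in gts], dtype=int)
    gt_free = np.ones(len(gts), dtype=bool)
    tp = np.zeros(len(dets), dtype=bool)
    for i in order:
        d = dets[i]
        cand = np.flatnonzero(gt_free & (gt_cls == d.class_id))
        if len(cand) == 0:
            continue
        ious = iou_xyxy(np.asarray(d.box)[None], gt_boxes[cand])[0]
        j = int(ious.argmax())
        if ious[j] >= iou_thresh:
            gt_free[cand[j]] = False
            tp[i] = True
    rec = MatchRecord(
        np.array([d.score for d in dets], dtype=np.float64),
        np.array([d.class_id for d in dets], dtype=int),
        tp, {})
    for c in gt_cls:
        rec.gt_per_class[int(c)] = rec.gt_per_class.get(int(c), 0) + 1
    return rec


def precision_recall(rec: MatchRecord, class_id: int | None = None
                     ) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); zero denominators yield 0."""
    tp, fp, fn = rec.counts(class_id)
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    return float(p), float(r)


def average_precision(rec: MatchRecord, class_id: int,
                      method: str = "continuous") -> float:
    """AP of one class from the ranked detections.

    ``continuous`` integrates the monotone precision envelope over every
    recall step (all-point interpolation); ``11point`` averages the
    envelope at recalls 0, 0.1, ..., 1.  A class without ground truth has
    no defined AP and raises.
    """
    n_gt = rec.gt_per_class.get(class_id, 0)
    if n_gt == 0:
        raise ValueError(f"class {class_id} has no ground truth")
    sel = rec.classes == class_id
    if not sel.any():
        return 0.0
    order = np.argsort(-rec.scores[sel], kind="stable")
    tp = rec.tp[sel][order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / n_gt
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1)

    r = np.concatenate([[0.0], recall, [recall[-1] if len(recall) else 0.0]])
    p = np.concatenate([[1.0], precision, [0.0]])
    p = np.maximum.accumulate(p[::-1])[::-1]  # monotone envelope
    if method == "continuous":
        steps = np.flatnonzero(np.diff(r) > 0)
        return float(np.sum((r[steps + 1] - r[steps]) * p[steps + 1]))
    if method == "11point":
        return float(np.mean([p[r >= t].max() if (r >= t).any() else 0.0
                              for t in np.linspace(0, 1, 11)]))
    raise ValueError(method)


def mean_ap(aps: dict[int, float] | list[float]) -> float:
    """Unweighted mean over classes."""
    vals = list(aps.values()) if isinstance(aps, dict) else list(aps)
    if not vals:
        return 0.0
    return float(np.mean(vals))


def confusion_matrix(dets_per_image: list[list[Detection]],
                     gts_per_image: list[list[GroundTruth]],
                     num_classes: int, conf_thresh: float = 0.25,
                     iou_thresh: float = 0.45,
                     normalize: bool = True) -> np.ndarray:
    """(K+1) x (K+1) matrix, rows = predicted class (+background),
    columns = true class (+background).

    Per image, detections above ``conf_thresh`` are paired to ground
    truths greedily by descending IoU (each side used once) when IoU
    reaches the threshold; matched pairs increment (pred, true),
    unmatched ground truths the background row, unmatched detections the
    background column.  Columns are normalized to sum to one where
    nonzero.
    """
    if not (0.0 <= conf_thresh <= 1.0 and 0.0 <= iou_thresh <= 1.0):
        raise ValueError("thresholds must lie in [0,1]")
    k = num_classes
    mat = np.zeros((k + 1, k + 1), dtype=np.float64)
    for dets, gts in zip(dets_per_image, gts_per_image):
        dets = [d for d in dets if d.score >= conf_thresh]
        if gts:
            gt_boxes = np.array([g[1] for g in gts], dtype=np.float64)
        det_used = np.zeros(len(dets), dtype=bool)
        gt_used = np.zeros(len(gts), dtype=bool)
        if dets and gts:
            d_boxes = np.array([d.box for d in dets], dtype=np.float64)
            ious = iou_xyxy(d_boxes, gt_boxes)
            pairs = np.argwhere(ious >= iou_thresh)
            for di, gi in pairs[np.argsort(-ious[ious >= iou_thresh])]:
                if det_used[di] or gt_used[gi]:
                    continue
                det_used[di] = gt_used[gi] = True
                mat[dets[di].class_id, gts[gi][0]] += 1
        for gi, g in enumerate(gts):
            if not gt_used[gi]:
                mat[k, g[0]] += 1  # background FN: missed ground truth
        for di, d in enumerate(dets):
            if not det_used[di]:
                mat[d.class_id, k] += 1  # spurious detection
    if normalize:
        sums = mat.sum(axis=0, keepdims=True)
        mat = np.divide(mat, sums, out=np.zeros_like(mat), where=sums > 0)
    return mat


@dataclass
class EvalReport:
    """Per-class and overall detection metrics plus the confusion matrix."""

    precision: dict  # class id (or "all") -> P
    recall: dict
    ap: dict         # class id -> AP at the matching IoU threshold
    map50: float
    confusion: np.ndarray
    classes_without_gt: list[int] = field(default_factory=list)

    def summary(self, names: list[str] | None = None) -> str:
        lines = [f"{'class':>14} {'P':>7} {'R':>7} {'AP50':>7}"]
        for c in sorted(self.ap):
            label = names[c] if names else str(c)
            lines.append(f"{label:>14} {self.precision[c]:7.3f} "
                         f"{self.recall[c]:7.3f} {self.ap[c]:7.3f}")
        lines.append(f"{'all':>14} {self.precision['all']:7.3f} "
                     f"{self.recall['all']:7.3f} {self.map50:7.3f}")
        return "\n".join(lines)


def evaluate_detections(dets_per_image: list[list[Detection]],
                        gts_per_image: list[list[GroundTruth]],
                        num_classes: int, iou_thresh: float = 0.5,
                        pr_conf_thresh: float = 0.25) -> EvalReport:
    """Dataset-level report from per-image detections and ground truths.

    AP uses every detection (the full score sweep); the headline P and R
    are reported at ``pr_conf_thresh``.  Classes without any ground truth
    are excluded from the mean and flagged.
    """
    full = MatchRecord()
    thr = MatchRecord()
    for dets, gts in zip(dets_per_image, gts_per_image):
        full = full.merge(match_detections(dets, gts, iou_thresh))
        thr = thr.merge(match_detections(
            [d for d in dets if d.score >= pr_conf_thresh], gts, iou_thresh))
    precision, recall, ap = {}, {}, {}
    skipped = []
    for c in range(num_classes):
        if full.gt_per_class.get(c, 0) == 0:
            skipped.append(c)
            continue
        precision[c], recall[c] = precision_recall(thr, c)
        ap[c] = average_precision(full, c)
    precision["all"], recall["all"] = precision_recall(thr)
    conf = confusion_matrix(dets_per_image, gts_per_image, num_classes,
                            conf_thresh=pr_conf_thresh)
    return EvalReport(precision, recall, ap, mean_ap(ap), conf, skipped)
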