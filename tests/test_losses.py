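"""CIoU, anchor-ratio target assignment and the composite loss."""

import numpy as np
import pytest

from pestdet import autograd as ag
from pestdet.autograd import Tensor
from pestdet.boxes import NormBox
from pestdet.losses import (ANCHOR_RATIO_THRESH, assign_batch, assign_targets,
                            ciou, compute_loss, _ciou_tensor)
from pestdet.network import ModelSpec


def ciou_reference(a, b):
    """Independent CIoU evaluation (separate authorship from the library
    routine): every quantity computed from first principles in float64."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    inter_w = min(ax2, bx2) - max(ax1, bx1)
    inter_h = min(ay2, by2) - max(ay1, by1)
    inter = max(inter_w, 0.0) * max(inter_h, 0.0)
    area_a = (ax2 - ax1) * (ay2 - ay1)
    area_b = (bx2 - bx1) * (by2 - by1)
    iou = inter / (area_a + area_b - inter + 1e-9)
    # squared center distance over squared enclosing diagonal
    rho2 = ((ax1 + ax2) / 2 - (bx1 + bx2) / 2) ** 2 \
        + ((ay1 + ay2) / 2 - (by1 + by2) / 2) ** 2
    c2 = (max(ax2, bx2) - min(ax1, bx1)) ** 2 \
        + (max(ay2, by2) - min(ay1, by1)) ** 2 + 1e-9
    v = 4 / np.pi ** 2 * (np.arctan((bx2 - bx1) / (by2 - by1))
                          - np.arctan((ax2 - ax1) / (ay2 - ay1))) ** 2
    alpha = v / (1 - iou + v + 1e-9)
    return iou - rho2 / c2 - alpha * v


class TestCIoU:
    def test_identical_boxes_give_one(self):
        assert ciou((0, 0, 10, 20), (0, 0, 10, 20)) == pytest.approx(1.0)

    def test_far_same_shape_boxes_negative(self):
        # IoU is 0 and the center-distance term dominates
        assert ciou((0, 0, 10, 10), (500, 500, 510, 510)) < 0

    def test_shared_center_and_aspect_equals_iou(self):
        # concentric squares: penalties vanish, CIoU == IoU
        a, b = (0, 0, 10, 10), (-5, -5, 15, 15)
        inter, union = 100.0, 400.0
        assert ciou(a, b) == pytest.approx(inter / union, abs=1e-6)

    def test_matches_independent_reference_on_random_pairs(self, rng):
        for _ in range(1000):
            x1, y1 = rng.uniform(0, 50, 2)
            w, h = rng.uniform(1, 60, 2)
            a = (x1, y1, x1 + w, y1 + h)
            x1, y1 = rng.uniform(0, 50, 2)
            w, h = rng.uniform(1, 60, 2)
            b = (x1, y1, x1 + w, y1 + h)
            assert ciou(a, b) == pytest.approx(ciou_reference(a, b), abs=1e-9)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            ciou((0, 0, 0, 10), (0, 0, 5, 5))

    def test_range_bound(self, rng):
        for _ in range(200):
            a = tuple(np.sort(rng.uniform(0, 40, 2))) \
                + tuple(np.sort(rng.uniform(41, 80, 2)))
            b = tuple(np.sort(rng.uniform(0, 40, 2))) \
                + tuple(np.sort(rng.uniform(41, 80, 2)))
            boxa = (a[0], a[2], a[1], a[3])
            boxb = (b[0], b[2], b[1], b[3])
            # exact range of the formula: IoU in [0,1], center-distance
            # penalty < 1, aspect penalty < 1, so CIoU lies in (-2, 1]
            assert -2 < ciou(boxa, boxb) <= 1

    def test_tensor_version_agrees_with_scalar(self, rng):
        cs = rng.uniform(2, 10, (50, 4))
        ct = rng.uniform(2, 10, (50, 4))
        got = _ciou_tensor(Tensor(cs.astype(np.float32)), ct).data
        for k in range(50):
            a = (cs[k, 0] - cs[k, 2] / 2, cs[k, 1] - cs[k, 3] / 2,
                 cs[k, 0] + cs[k, 2] / 2, cs[k, 1] + cs[k, 3] / 2)
            b = (ct[k, 0] - ct[k, 2] / 2, ct[k, 1] - ct[k, 3] / 2,
                 ct[k, 0] + ct[k, 2] / 2, ct[k, 1] + ct[k, 3] / 2)
            assert got[k] == pytest.approx(ciou(a, b), abs=2e-4)

    def test_tensor_gradient_finite_difference(self, rng):
        pred = Tensor(rng.uniform(3, 8, (6, 4)).astype(np.float32),
                      requires_grad=True)
        target = rng.uniform(3, 8, (6, 4))
        loss = (1.0 - _ciou_tensor(pred, target)).sum()
        loss.backward()
        eps = 1e-2
        for k in [(0, 0), (2, 1), (4, 2), (5, 3)]:
            orig = pred.data[k]
            pred.data[k] = orig + eps
            with ag.no_grad():
                fp = (1.0 - _ciou_tensor(pred, target)).sum().item()
            pred.data[k] = orig - eps
            with ag.no_grad():
                fm = (1.0 - _ciou_tensor(pred, target)).sum().item()
            pred.data[k] = orig
            assert (fp - fm) / (2 * eps) == pytest.approx(
                float(pred.grad[k]), abs=2e-2)


@pytest.fixture(scope="module")
def spec():
    return ModelSpec(input_size=64)


class TestAssignment:
    def test_exact_anchor_match_assigned_at_that_scale(self, spec):
        s_idx, a_idx = 1, 0  # anchor (16, 24) at stride 8
        aw, ah = spec.anchors[s_idx][a_idx]
        label = NormBox(2, 0.5, 0.5, aw / 64, ah / 64)
        asg = assign_targets([label], spec)
        sa = asg.per_scale[s_idx]
        assert a_idx in sa.anchor
        assert asg.num_unassigned_labels == 0

    def test_oversized_label_unassigned_everywhere(self, spec):
        label = NormBox(0, 0.5, 0.5, 1.0, 1.0)  # 64 px vs largest anchor 220
        # ratio to every anchor exceeds 4 somewhere? the largest anchors fit;
        # use a spec whose anchors are all tiny instead
        small = spec.with_anchors([[(1, 1)] * 3] * 4)
        asg = assign_targets([label], small)
        assert all(len(s) == 0 for s in asg.per_scale)
        assert asg.num_unassigned_labels == 1

    def test_containing_cell_plus_two_neighbors(self, spec):
        label = NormBox(0, 0.33, 0.61, 0.25, 0.25)
        asg = assign_targets([label], spec)
        for sa in asg.per_scale:
            per_anchor = {}
            for a, i, j in zip(sa.anchor, sa.cell_i, sa.cell_j):
                per_anchor.setdefault(a, []).append((i, j))
            for cells in per_anchor.values():
                assert len(cells) == 3  # center + nearest x + nearest y
                assert len(set(cells)) == 3

    def test_matches_brute_force_enumeration(self, rng, spec):
        """Re-derive the assignment by enumerating every (scale, anchor)
        pair and applying the printed rule directly."""
        labels = [NormBox(int(rng.integers(0, 5)),
                          float(rng.uniform(0.15, 0.85)),
                          float(rng.uniform(0.15, 0.85)),
                          float(rng.uniform(0.05, 0.6)),
                          float(rng.uniform(0.05, 0.6))) for _ in range(12)]
        asg = assign_targets([labels[k] for k in range(12)], spec)
        for s_idx, (stride, anchors) in enumerate(
                zip(spec.strides, spec.anchors)):
            gw = 64 // stride
            want = set()
            for lb in labels:
                cx, cy = lb.cx * gw, lb.cy * gw
                w, h = lb.w * gw, lb.h * gw
                for a_idx, (aw, ah) in enumerate(anchors):
                    aw, ah = aw / stride, ah / stride
                    ratio = max(w / aw, aw / w, h / ah, ah / h)
                    if ratio >= ANCHOR_RATIO_THRESH:
                        continue
                    gj = int(np.clip(np.floor(cx), 0, gw - 1))
                    gi = int(np.clip(np.floor(cy), 0, gw - 1))
                    cells = {(gi, gj)}
                    if cx - np.floor(cx) < 0.5 and cx > 1 and gj - 1 >= 0:
                        cells.add((gi, gj - 1))
                    elif cx - np.floor(cx) >= 0.5 and cx < gw - 1 \
                            and gj + 1 < gw:
                        cells.add((gi, gj + 1))
                    if cy - np.floor(cy) < 0.5 and cy > 1 and gi - 1 >= 0:
                        cells.add((gi - 1, gj))
                    elif cy - np.floor(cy) >= 0.5 and cy < gw - 1 \
                            and gi + 1 < gw:
                        cells.add((gi + 1, gj))
                    for ci, cj in cells:
                        want.add((a_idx, ci, cj, lb.class_id))
            sa = asg.per_scale[s_idx]
            got = set(zip(sa.anchor.tolist(), sa.cell_i.tolist(),
                          sa.cell_j.tolist(), sa.cls.tolist()))
            assert got == want

    def test_batch_indices_tracked(self, spec):
        asg = assign_batch([[NormBox(0, 0.5, 0.5, 0.3, 0.3)],
                            [NormBox(1, 0.2, 0.2, 0.3, 0.3)]], spec)
        images = np.concatenate([s.image for s in asg.per_scale])
        assert set(images.tolist()) == {0, 1}


class TestCompositeLoss:
    def _raw(self, spec, batch=1, fill=0.0, grad=True):
        k = spec.num_classes
        return [Tensor(np.full((batch, 3, 64 // s, 64 // s, 5 + k), fill,
                               np.float32), requires_grad=grad)
                for s in spec.strides]

    def test_total_is_exact_sum_of_components(self, rng, spec):
        labels = [[NormBox(1, 0.4, 0.6, 0.3, 0.25)]]
        raw = [Tensor(rng.standard_normal(t.shape).astype(np.float32),
                      requires_grad=True) for t in self._raw(spec)]
        rep = compute_loss(raw, assign_batch(labels, spec), spec)
        assert rep.total == rep.loss_box + rep.loss_object + rep.loss_class
        assert rep.loss_box >= 0 and rep.loss_object >= 0 \
            and rep.loss_class >= 0

    def test_empty_assignment_keeps_objectness_term(self, spec):
        rep = compute_loss(self._raw(spec), assign_batch([[]], spec), spec)
        assert rep.loss_box == 0 and rep.loss_class == 0
        assert rep.loss_object > 0

    def test_perfect_predictions_drive_total_to_zero(self, spec):
        """Raw values decoding exactly to the target with saturated logits:
        every component becomes negligible."""
        label = NormBox(2, 0.5, 0.5, 0.25, 0.25)
        asg = assign_batch([[label]], spec)
        raw = self._raw(spec, fill=-40.0, grad=False)  # objectness ~ 0
        for sa, t, stride, anchors in zip(asg.per_scale, raw, spec.strides,
                                          spec.anchors):
            for n in range(len(sa)):
                b, a = sa.image[n], sa.anchor[n]
                i, j = sa.cell_i[n], sa.cell_j[n]
                tx, ty, tw, th = sa.tbox[n]
                aw, ah = np.array(anchors[a]) / stride
                # invert the decode transform
                sx = (tx + 0.5) / 2
                sy = (ty + 0.5) / 2
                swv = np.sqrt(tw / aw) / 2
                shv = np.sqrt(th / ah) / 2
                logit = lambda p: np.log(p / (1 - p))
                t.data[b, a, i, j, 0] = logit(np.clip(sx, 1e-6, 1 - 1e-6))
                t.data[b, a, i, j, 1] = logit(np.clip(sy, 1e-6, 1 - 1e-6))
                t.data[b, a, i, j, 2] = logit(np.clip(swv, 1e-6, 1 - 1e-6))
                t.data[b, a, i, j, 3] = logit(np.clip(shv, 1e-6, 1 - 1e-6))
                t.data[b, a, i, j, 4] = 40.0   # objectness -> 1 (CIoU ~ 1)
                t.data[b, a, i, j, 5:] = -40.0
                t.data[b, a, i, j, 5 + sa.cls[n]] = 40.0
        rep = compute_loss(raw, asg, spec)
        assert rep.loss_box < 1e-3
        assert rep.loss_class < 1e-6
        assert rep.loss_object < 1e-3
        assert rep.total < 2e-3

    def test_box_loss_decreases_monotonically_toward_target(self, spec):
        """Sweep a predicted box along a straight path to its target: the
        box term must strictly decrease at every step."""
        label = NormBox(0, 0.5, 0.5, 0.3, 0.3)
        asg = assign_batch([[label]], spec)
        losses = []
        # offsets stay inside the decode transform's representable window
        # (predicted center offset is 2*sigmoid - 0.5, i.e. (-0.5, 1.5))
        for offset in np.linspace(0.4, 0.0, 9):
            raw = self._raw(spec, fill=0.0, grad=False)
            sa = asg.per_scale[1]
            n = 0
            b, a = sa.image[n], sa.anchor[n]
            i, j = sa.cell_i[n], sa.cell_j[n]
            tx, ty, tw, th = sa.tbox[n]
            aw, ah = np.array(spec.anchors[1][a]) / spec.strides[1]
            logit = lambda p: np.log(p / (1 - p))
            sx = np.clip((tx - offset + 0.5) / 2, 1e-6, 1 - 1e-6)
            raw[1].data[b, a, i, j, 0] = logit(sx)
            raw[1].data[b, a, i, j, 1] = logit(np.clip((ty + 0.5) / 2,
                                                       1e-6, 1 - 1e-6))
            raw[1].data[b, a, i, j, 2] = logit(np.sqrt(tw / aw) / 2)
            raw[1].data[b, a, i, j, 3] = logit(np.sqrt(th / ah) / 2)
            only_scale1 = [raw[1]]
            sub_spec = spec
            rep = compute_loss(raw, asg, sub_spec)
            losses.append(rep.loss_box)
        diffs = np.diff(losses)
        assert (diffs < 0).all()

    def test_gradient_reaches_raw_predictions(self, rng, spec):
        labels = [[NormBox(0, 0.5, 0.5, 0.3, 0.3)]]
        raw = [Tensor(rng.standard_normal(t.shape).astype(np.float32) * 0.1,
                      requires_grad=True) for t in self._raw(spec)]
        rep = compute_loss(raw, assign_batch(labels, spec), spec)
        rep.total_tensor.backward()
        assert all(t.grad is not None and np.isfinite(t.grad).all()
                   for t in raw)
        assert any(np.abs(t.grad).max() > 0 for t in raw)
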