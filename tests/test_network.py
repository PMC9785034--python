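"""Detector assembly: focus stem, grid shapes, decode, NMS, anchors."""

import warnings

import numpy as np
import pytest

from pestdet.boxes import Detection, iou_xyxy
from pestdet.network import (ModelSpec, build_model, compute_anchors, decode,
                             focus_inverse, focus_transform, forward,
                             load_checkpoint, nms, proposed_spec,
                             save_checkpoint, small_baseline_spec)


class TestFocus:
    def test_constant_image_gives_constant_channels(self):
        img = np.full((64, 64, 3), 7.0, np.float32)
        out = focus_transform(img)
        assert out.shape == (12, 32, 32)
        np.testing.assert_allclose(out, 7.0)

    def test_bijective_reassembly(self, rng):
        img = rng.random((64, 48, 3)).astype(np.float32)
        np.testing.assert_array_equal(focus_inverse(focus_transform(img)), img)

    def test_spatial_halving_at_working_size(self, rng):
        out = focus_transform(rng.random((512, 512, 3)).astype(np.float32))
        assert out.shape == (12, 256, 256)

    def test_odd_dimensions_rejected(self):
        with pytest.raises(ValueError):
            focus_transform(np.zeros((65, 64, 3), np.float32))


class TestModelShapes:
    def test_four_scales_and_stride_arithmetic(self, tiny_model):
        raw = forward(tiny_model, np.zeros((1, 3, 64, 64), np.float32))
        assert [r.shape for r in raw] == [
            (1, 3, 16, 16, 10), (1, 3, 8, 8, 10),
            (1, 3, 4, 4, 10), (1, 3, 2, 2, 10)]
        assert all(np.isfinite(r).all() for r in raw)

    def test_doubling_input_quadruples_cells(self, tiny_model):
        a = forward(tiny_model, np.zeros((1, 3, 64, 64), np.float32))
        b = forward(tiny_model, np.zeros((1, 3, 128, 128), np.float32))
        for ra, rb in zip(a, b):
            assert rb.shape[2] * rb.shape[3] == 4 * ra.shape[2] * ra.shape[3]

    def test_baseline_has_three_scales(self):
        model = build_model(small_baseline_spec(input_size=64), seed=0)
        raw = forward(model, np.zeros((1, 3, 64, 64), np.float32))
        assert [r.shape[2] for r in raw] == [8, 4, 2]

    def test_invalid_input_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            forward(tiny_model, np.zeros((1, 3, 60, 60), np.float32))
        with pytest.raises(ValueError):
            forward(tiny_model, np.zeros((1, 4, 64, 64), np.float32))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec(input_size=100)
        with pytest.raises(ValueError):
            ModelSpec(repeats=(1, 2, 3))
        with pytest.raises(ValueError):
            ModelSpec(norm_stats="layer")


class TestDecode:
    def _zero_raw(self, spec):
        k = spec.num_classes
        return [np.zeros((3, spec.input_size // s, spec.input_size // s, 5 + k),
                         np.float32) for s in spec.strides]

    def test_zero_logits_center_and_anchor_size(self, tiny_spec):
        """sigmoid(0)=0.5 plugged in: center=(0.5+cell)*stride, size=anchor."""
        raw = self._zero_raw(tiny_spec)
        dets = decode(raw, tiny_spec, conf_thresh=0.0)
        d = dets[0]  # first emitted: scale 0, anchor 0, cell (0,0), class 0
        stride = tiny_spec.strides[0]
        aw, ah = tiny_spec.anchors[0][0]
        cx, cy = (d.box[0] + d.box[2]) / 2, (d.box[1] + d.box[3]) / 2
        assert cx == pytest.approx(0.5 * stride)
        assert cy == pytest.approx(0.5 * stride)
        assert d.box[2] - d.box[0] == pytest.approx(aw)
        assert d.box[3] - d.box[1] == pytest.approx(ah)
        assert d.score == pytest.approx(0.25)  # sigmoid(0)^2

    def test_conf_one_empty(self, tiny_spec):
        assert decode(self._zero_raw(tiny_spec), tiny_spec, 1.0) == []

    def test_matches_straight_line_reimplementation(self, rng, tiny_spec):
        raw = [rng.standard_normal(r.shape).astype(np.float32)
               for r in self._zero_raw(tiny_spec)]
        got = decode(raw, tiny_spec, conf_thresh=0.3)
        want = []
        sig = lambda v: 1 / (1 + np.exp(-v))
        for arr, stride, anchors in zip(raw, tiny_spec.strides,
                                        tiny_spec.anchors):
            _, h, w, _ = arr.shape
            for a in range(3):
                for i in range(h):
                    for j in range(w):
                        row = arr[a, i, j]
                        cx = (2 * sig(row[0]) - 0.5 + j) * stride
                        cy = (2 * sig(row[1]) - 0.5 + i) * stride
                        bw = (2 * sig(row[2])) ** 2 * anchors[a][0]
                        bh = (2 * sig(row[3])) ** 2 * anchors[a][1]
                        for c in range(tiny_spec.num_classes):
                            score = sig(row[4]) * sig(row[5 + c])
                            if score >= 0.3:
                                want.append((c, score, cx, cy, bw, bh))
        assert len(got) == len(want)
        for d, (c, score, cx, cy, bw, bh) in zip(got, want):
            assert d.class_id == c
            assert d.score == pytest.approx(score, rel=1e-5)
            assert (d.box[0] + d.box[2]) / 2 == pytest.approx(cx, rel=1e-4)
            assert d.box[2] - d.box[0] == pytest.approx(bw, rel=1e-3)


class TestNMS:
    def test_single_detection_unchanged(self):
        d = Detection(0, 0.7, (0, 0, 10, 10))
        assert nms([d]) == [d]

    def test_duplicate_boxes_keep_highest_score(self):
        a = Detection(1, 0.9, (0, 0, 10, 10))
        b = Detection(1, 0.8, (0, 0, 10, 10))
        assert nms([b, a]) == [a]

    def test_different_classes_never_suppress(self):
        a = Detection(0, 0.9, (0, 0, 10, 10))
        b = Detection(1, 0.8, (0, 0, 10, 10))
        assert len(nms([a, b])) == 2

    def _random_dets(self, rng, n):
        out = []
        for _ in range(n):
            x1, y1 = rng.uniform(0, 80, 2)
            w, h = rng.uniform(5, 30, 2)
            out.append(Detection(int(rng.integers(0, 3)),
                                 float(rng.uniform(0.05, 1.0)),
                                 (x1, y1, x1 + w, y1 + h)))
        return out

    def test_matches_quadratic_brute_force(self, rng):
        dets = self._random_dets(rng, 200)
        got = nms(dets, 0.5)
        # brute force: independently per class, repeatedly take the best
        # remaining and delete everything overlapping it
        want = []
        for cls in sorted({d.class_id for d in dets}):
            pool = sorted([d for d in dets if d.class_id == cls],
                          key=lambda d: -d.score)
            while pool:
                best = pool.pop(0)
                want.append(best)
                pool = [d for d in pool
                        if iou_xyxy(np.array(best.box)[None],
                                    np.array(d.box)[None])[0, 0] <= 0.5]
        assert sorted(got, key=lambda d: (d.class_id, -d.score)) == \
            sorted(want, key=lambda d: (d.class_id, -d.score))

    def test_no_surviving_overlap_above_threshold(self, rng):
        survivors = nms(self._random_dets(rng, 300), 0.45)
        for i, a in enumerate(survivors):
            for b in survivors[i + 1:]:
                if a.class_id == b.class_id:
                    iou = iou_xyxy(np.array(a.box)[None],
                                   np.array(b.box)[None])[0, 0]
                    assert iou <= 0.45 + 1e-12


class TestAnchors:
    def test_degenerate_identical_boxes(self):
        wh = np.full((50, 2), 51.2)
        anchors = compute_anchors(wh, 12, seed=0)
        np.testing.assert_allclose(anchors, 51.2)

    def test_planted_clusters_recovered_within_five_percent(self, rng):
        centers = np.array([[8, 10], [14, 9], [12, 20], [22, 28], [35, 24],
                            [28, 44], [50, 40], [42, 70], [75, 60],
                            [90, 110], [150, 130], [230, 215]], float)
        wh = np.vstack([c * rng.uniform(0.98, 1.02, (40, 2)) for c in centers])
        anchors = compute_anchors(wh, 12, seed=0).reshape(12, 2)
        planted = centers[np.argsort(centers[:, 0] * centers[:, 1])]
        rel = np.abs(anchors - planted) / planted
        assert rel.max() < 0.05

    def test_output_sorted_by_area(self, rng):
        wh = rng.uniform(4, 200, (100, 2))
        anchors = compute_anchors(wh, 12, seed=1).reshape(12, 2)
        areas = anchors[:, 0] * anchors[:, 1]
        assert (np.diff(areas) >= -1e-9).all()

    def test_fallback_on_too_few_boxes(self):
        with pytest.warns(UserWarning, match="default anchor table"):
            anchors = compute_anchors(np.array([[10.0, 12.0]]), 12, seed=0)
        assert anchors.shape == (4, 3, 2)


def test_checkpoint_roundtrip(tmp_path, tiny_model, rng):
    path = tmp_path / "model.npz"
    save_checkpoint(path, tiny_model)
    clone = load_checkpoint(path)
    assert clone.spec == tiny_model.spec
    x = rng.random((1, 3, 64, 64)).astype(np.float32)
    np.testing.assert_allclose(forward(clone, x)[0],
                               forward(tiny_model, x)[0], atol=1e-6)


def test_layer_counts_proposed_vs_baseline():
    prop = build_model(proposed_spec(), seed=0)
    base = build_model(small_baseline_spec(), seed=0)
    assert prop.layer_count() - base.layer_count() == 18
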