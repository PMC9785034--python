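"""Precision/recall/AP/mAP definitions and the background confusion matrix."""

import numpy as np
import pytest

from pestdet.boxes import Detection, iou_xyxy
from pestdet.metrics import (MatchRecord, average_precision, confusion_matrix,
                             evaluate_detections, match_detections, mean_ap,
                             precision_recall)


def det(cls, score, x1, y1, x2, y2):
    return Detection(cls, score, (x1, y1, x2, y2))


def gt(cls, x1, y1, x2, y2):
    return (cls, np.array([x1, y1, x2, y2], float))


class TestMatching:
    def test_identical_boxes_all_tp(self):
        gts = [gt(0, 0, 0, 10, 10), gt(1, 20, 20, 35, 35)]
        dets = [det(0, 0.9, 0, 0, 10, 10), det(1, 0.8, 20, 20, 35, 35)]
        rec = match_detections(dets, gts)
        assert rec.tp.all()
        assert rec.counts() == (2, 0, 0)

    def test_no_detections_all_fn(self):
        rec = match_detections([], [gt(0, 0, 0, 5, 5)] * 3)
        assert rec.counts() == (0, 0, 3)

    def test_each_gt_matched_at_most_once(self):
        gts = [gt(0, 0, 0, 10, 10)]
        dets = [det(0, 0.9, 0, 0, 10, 10), det(0, 0.8, 0, 0, 10, 10)]
        rec = match_detections(dets, gts)
        assert rec.counts() == (1, 1, 0)

    def test_wrong_class_never_matches(self):
        rec = match_detections([det(1, 0.9, 0, 0, 10, 10)],
                               [gt(0, 0, 0, 10, 10)])
        assert rec.counts() == (0, 1, 1)

    def test_matches_brute_force_on_random_instances(self, rng):
        """Replay the greedy rule with an independent loop implementation."""
        for _ in range(10):
            gts, dets = [], []
            for _ in range(rng.integers(1, 20)):
                x, y = rng.uniform(0, 60, 2)
                w, h = rng.uniform(4, 25, 2)
                gts.append(gt(int(rng.integers(0, 3)), x, y, x + w, y + h))
            for _ in range(rng.integers(1, 30)):
                x, y = rng.uniform(0, 60, 2)
                w, h = rng.uniform(4, 25, 2)
                dets.append(det(int(rng.integers(0, 3)),
                                float(rng.uniform(0, 1)), x, y, x + w, y + h))
            rec = match_detections(dets, gts, 0.5)
            free = [True] * len(gts)
            want_tp = [False] * len(dets)
            for idx in sorted(range(len(dets)), key=lambda i: -dets[i].score):
                best_iou, best_j = 0.0, -1
                for j, g in enumerate(gts):
                    if not free[j] or g[0] != dets[idx].class_id:
                        continue
                    iou = iou_xyxy(np.array(dets[idx].box)[None],
                                   g[1][None])[0, 0]
                    if iou > best_iou:
                        best_iou, best_j = iou, j
                if best_iou >= 0.5:
                    free[best_j] = False
                    want_tp[idx] = True
            assert rec.tp.tolist() == want_tp


class TestPrecisionRecall:
    def test_printed_definitions(self):
        rec = MatchRecord(np.linspace(1, 0.1, 4), np.zeros(4, int),
                          np.array([True, True, True, False]),
                          {0: 10})
        p, r = precision_recall(rec, 0)
        assert p == pytest.approx(3 / 4)   # TP=3, FP=1
        rec2 = MatchRecord(np.linspace(1, 0.1, 8), np.zeros(8, int),
                           np.array([True] * 8), {0: 10})
        _, r2 = precision_recall(rec2, 0)
        assert r2 == pytest.approx(8 / 10)  # TP=8, FN=2

    def test_perfect_detections(self):
        rec = MatchRecord(np.array([0.9, 0.8]), np.array([0, 1]),
                          np.array([True, True]), {0: 1, 1: 1})
        assert precision_recall(rec) == (1.0, 1.0)

    def test_zero_denominators_define_zero(self):
        rec = MatchRecord(np.zeros(0), np.zeros(0, int),
                          np.zeros(0, bool), {0: 0})
        assert precision_recall(rec, 0) == (0.0, 0.0)


class TestAveragePrecision:
    def test_single_true_positive_full_ap(self):
        rec = MatchRecord(np.array([0.9]), np.array([0]),
                          np.array([True]), {0: 1})
        assert average_precision(rec, 0) == pytest.approx(1.0)

    def test_against_rectangle_summation_oracle(self):
        """Scores .9...5 with flags TP,FP,TP,FP,TP over 3 ground truths:
        integrate the monotone envelope by explicit rectangles."""
        flags = np.array([True, False, True, False, True])
        rec = MatchRecord(np.array([0.9, 0.8, 0.7, 0.6, 0.5]),
                          np.zeros(5, int), flags, {0: 3})
        # rank-by-rank precision/recall points
        tp_cum = np.cumsum(flags)
        fp_cum = np.cumsum(~flags)
        recalls = tp_cum / 3
        precisions = tp_cum / (tp_cum + fp_cum)
        want, prev_r = 0.0, 0.0
        for k in range(5):
            if recalls[k] > prev_r:
                env = max(precisions[k:])  # envelope at this recall step
                want += (recalls[k] - prev_r) * env
                prev_r = recalls[k]
        assert average_precision(rec, 0) == pytest.approx(want, abs=1e-12)

    def test_invariant_to_monotone_score_transforms(self, rng):
        scores = rng.uniform(0.1, 0.9, 20)
        flags = rng.random(20) > 0.5
        rec1 = MatchRecord(scores, np.zeros(20, int), flags, {0: 12})
        rec2 = MatchRecord(scores ** 3, np.zeros(20, int), flags, {0: 12})
        assert average_precision(rec1, 0) == pytest.approx(
            average_precision(rec2, 0))

    def test_class_without_gt_raises(self):
        rec = MatchRecord(np.zeros(0), np.zeros(0, int), np.zeros(0, bool), {})
        with pytest.raises(ValueError):
            average_precision(rec, 0)

    def test_eleven_point_variant_bounded(self, rng):
        scores = rng.uniform(0, 1, 30)
        flags = rng.random(30) > 0.4
        rec = MatchRecord(scores, np.zeros(30, int), flags, {0: 20})
        ap = average_precision(rec, 0, method="11point")
        assert 0.0 <= ap <= 1.0


def test_mean_ap_is_unweighted_mean():
    assert mean_ap({0: 1.0, 1: 0.5}) == pytest.approx(0.75)
    assert mean_ap({2: 0.5, 0: 1.0}) == pytest.approx(0.75)  # order-free
    assert mean_ap({}) == 0.0


class TestConfusionMatrix:
    def test_perfect_detections_identity_diagonal(self):
        dets = [[det(c, 0.9, c * 20, 0, c * 20 + 10, 10)] for c in range(3)]
        gts = [[gt(c, c * 20, 0, c * 20 + 10, 10)] for c in range(3)]
        mat = confusion_matrix(dets, gts, 3)
        np.testing.assert_allclose(np.diag(mat)[:3], 1.0)

    def test_zero_detections_fill_background_row(self):
        gts = [[gt(0, 0, 0, 10, 10), gt(1, 20, 0, 30, 10)]]
        mat = confusion_matrix([[]], gts, 2)
        assert mat[2, 0] == 1.0 and mat[2, 1] == 1.0

    def test_spurious_detection_hits_background_column(self):
        mat = confusion_matrix([[det(1, 0.9, 0, 0, 10, 10)]], [[]], 2,
                               normalize=False)
        assert mat[1, 2] == 1.0

    def test_columns_sum_to_one_where_nonzero(self, rng):
        dets, gts = [], []
        for _ in range(6):
            img_d, img_g = [], []
            for _ in range(rng.integers(0, 6)):
                x, y = rng.uniform(0, 50, 2)
                img_g.append(gt(int(rng.integers(0, 3)), x, y, x + 12, y + 12))
            for _ in range(rng.integers(0, 8)):
                x, y = rng.uniform(0, 50, 2)
                img_d.append(det(int(rng.integers(0, 3)),
                                 float(rng.uniform(0.3, 1)),
                                 x, y, x + 12, y + 12))
            dets.append(img_d)
            gts.append(img_g)
        mat = confusion_matrix(dets, gts, 3)
        sums = mat.sum(axis=0)
        for s in sums:
            assert s == pytest.approx(1.0) or s == 0.0

    def test_matches_brute_force_recount(self, rng):
        dets = [[det(0, 0.9, 0, 0, 10, 10), det(1, 0.6, 40, 40, 52, 52)]]
        gts = [[gt(0, 1, 1, 10, 10), gt(0, 40, 40, 50, 50)]]
        mat = confusion_matrix(dets, gts, 2, conf_thresh=0.25,
                               iou_thresh=0.45, normalize=False)
        # det0 matches gt0 (same class slot counts (0,0)); det1 overlaps gt1
        # enough (IoU (10*10)/(144+100-100) > .45) and counts (1, 0)
        assert mat[0, 0] == 1
        assert mat[1, 0] == 1
        assert mat.sum() == 2


def test_dataset_level_report(rng):
    gts = [[gt(0, 0, 0, 10, 10)], [gt(1, 5, 5, 25, 25)]]
    dets = [[det(0, 0.9, 0, 0, 10, 10)],
            [det(1, 0.8, 5, 5, 25, 25), det(1, 0.3, 60, 60, 80, 80)]]
    rep = evaluate_detections(dets, gts, num_classes=5)
    assert rep.ap[0] == pytest.approx(1.0)
    assert rep.map50 == pytest.approx(mean_ap(rep.ap))
    assert set(rep.classes_without_gt) == {2, 3, 4}
    assert 0.0 <= rep.precision["all"] <= 1.0
    assert "all" in rep.summary(["a", "b", "c", "d", "e"])
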