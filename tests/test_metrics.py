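"""Confusion-matrix metrics, point-count IoU metrics and VOC AP."""

import itertools

import numpy as np
import pytest

from tonguemap.dataset import ClassLabel, LabelMask
from tonguemap.imaging import GridSpec
from tonguemap.metrics import (APResult, ConfusionMatrix, Detection,
                               ImageSegMetrics, SegCounts, class_metrics,
                               evaluate_pointmaps, image_confidence,
                               macro_average, roc_auc, round_report,
                               seg_counts, voc_ap)
from tonguemap.pointmap import PointMap, PointRecord, ground_truth_pointmap
from tonguemap.reference import VGG16_CONFUSION


def _pointmap(labels, probs=None, source="img"):
    """Build a PointMap from an (n_rows, n_cols) label array."""
    labels = np.asarray(labels)
    n_rows, n_cols = labels.shape
    spec = GridSpec(n_cols, n_rows, overlapping=True, crop_w=4, crop_h=4)
    pts = []
    for i in range(n_rows):
        for j in range(n_cols):
            p = None if probs is None else np.asarray(probs[i][j], dtype=float)
            pts.append(PointRecord(j, i, 4.0 * j + 1, 4.0 * i + 1,
                                   ClassLabel(int(labels[i, j])), p))
    shape = (4 * n_rows + 4, 4 * n_cols + 4)
    return PointMap(source, spec, tuple(pts), shape)


class TestClassMetrics:
    def test_reference_confusion_matrix_metrics(self):
        cm = ConfusionMatrix(VGG16_CONFUSION)
        m = class_metrics(cm, ClassLabel.ABNORMAL)
        assert round_report(m.precision) == 0.935
        assert round_report(m.recall) == 0.986
        assert round_report(m.f1) == 0.960
        assert round_report(m.accuracy) == 0.967

    def test_perfect_classifier_scores_one(self):
        cm = ConfusionMatrix(np.diag([5, 7, 9]))
        for label in ClassLabel:
            m = class_metrics(cm, label)
            assert (m.precision, m.recall, m.f1, m.accuracy) == (1, 1, 1, 1)

    def test_hand_computed_counts(self):
        cm = ConfusionMatrix([[2, 1, 0], [0, 3, 0], [0, 0, 4]])
        m = class_metrics(cm, ClassLabel.ABNORMAL)
        assert m.precision == 1.0
        assert m.recall == pytest.approx(2 / 3)

    def test_one_vs_rest_accuracy_matches_binary_relabel_oracle(self):
        rng = np.random.default_rng(23)
        y_true = rng.integers(0, 3, 500)
        y_pred = rng.integers(0, 3, 500)
        cm = ConfusionMatrix.from_labels(y_true, y_pred)
        assert np.trace(cm.counts) == np.sum(y_true == y_pred)
        for label in ClassLabel:
            binary_acc = np.mean((y_true == int(label)) == (y_pred == int(label)))
            assert class_metrics(cm, label).accuracy == pytest.approx(binary_acc)

    def test_per_class_tp_sums_to_trace(self):
        cm = ConfusionMatrix(VGG16_CONFUSION)
        tps = [cm.binary_counts(c)[0] for c in ClassLabel]
        assert sum(tps) == np.trace(cm.counts)

    def test_zero_denominator_flagged_as_zero(self):
        cm = ConfusionMatrix([[0, 3, 0], [0, 5, 0], [0, 2, 0]])
        m = class_metrics(cm, ClassLabel.ABNORMAL)
        assert m.precision == 0.0 and m.recall == 0.0
        assert any("zero denominator" in f for f in m.flags)

    def test_csv_round_trip(self, tmp_path):
        cm = ConfusionMatrix(VGG16_CONFUSION)
        cm.to_csv(tmp_path / "cm.csv")
        assert np.array_equal(ConfusionMatrix.from_csv(tmp_path / "cm.csv").counts,
                              cm.counts)


class TestRocAuc:
    def test_perfect_separation(self):
        y = [1, 1, 0, 0]
        s = [0.9, 0.8, 0.2, 0.1]
        assert roc_auc(y, s, ClassLabel.NORMAL) == 1.0

    def test_constant_scores_give_half(self):
        assert roc_auc([1, 1, 0, 0], [0.5] * 4, ClassLabel.NORMAL) == 0.5

    def test_toy_set_pair_enumeration(self):
        y = [1, 1, 0, 0]
        s = [0.9, 0.8, 0.7, 0.85]
        assert roc_auc(y, s, ClassLabel.NORMAL) == 0.75

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(29)
        y = rng.integers(0, 2, 60)
        s = np.round(rng.random(60), 2)  # ties likely
        pos, neg = s[y == 1], s[y == 0]
        pairs = [(1.0 if a > b else 0.5 if a == b else 0.0)
                 for a, b in itertools.product(pos, neg)]
        assert roc_auc(y, s, ClassLabel.NORMAL) == pytest.approx(np.mean(pairs))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.2, 0.3], ClassLabel.NORMAL)


class TestSegCounts:
    def test_identical_maps_have_unit_iou(self):
        labels = np.array([[0, 1], [2, 0]])
        sc = seg_counts(_pointmap(labels), _pointmap(labels), ClassLabel.ABNORMAL)
        assert sc.g == sc.p == sc.i == 2
        assert sc.iou == 1.0

    def test_disjoint_maps_have_zero_iou(self):
        a = np.array([[0, 0], [1, 1]])
        b = np.array([[1, 1], [0, 0]])
        sc = seg_counts(_pointmap(a), _pointmap(b), ClassLabel.ABNORMAL)
        assert sc.i == 0 and sc.iou == 0.0

    def test_count_arithmetic(self):
        # G=10, P=8, I=6 -> S=12, tp=6, fp=2, fn=4, IoU=0.5
        sc = SegCounts(ClassLabel.NORMAL, g=10, p=8, i=6)
        assert (sc.s, sc.tp, sc.fp, sc.fn) == (12, 6, 2, 4)
        assert sc.iou == 0.5

    def test_invalid_intersection_rejected(self):
        with pytest.raises(ValueError):
            SegCounts(ClassLabel.NORMAL, g=3, p=2, i=4)

    def test_grid_mismatch_rejected(self):
        a = _pointmap(np.zeros((2, 2), int))
        b = _pointmap(np.zeros((2, 3), int))
        with pytest.raises(ValueError):
            seg_counts(a, b, ClassLabel.ABNORMAL)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_set_intersection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(2, 9)), int(rng.integers(2, 9)))
        gt = _pointmap(rng.integers(0, 3, shape))
        pred = _pointmap(rng.integers(0, 3, shape))
        for label in ClassLabel:
            g_set = {(i, j) for i in range(shape[0]) for j in range(shape[1])
                     if gt.labels[i, j] == int(label)}
            p_set = {(i, j) for i in range(shape[0]) for j in range(shape[1])
                     if pred.labels[i, j] == int(label)}
            sc = seg_counts(gt, pred, label)
            assert (sc.g, sc.p, sc.i) == (len(g_set), len(p_set),
                                          len(g_set & p_set))
            assert sc.s == len(g_set | p_set)


class TestImageMetricsAndMacro:
    def _metrics(self, g, p, i, label=ClassLabel.ABNORMAL, conf=0.9, img="a"):
        return ImageSegMetrics(img, label, SegCounts(label, g, p, i), conf)

    def test_precision_recall_from_counts(self):
        m = self._metrics(10, 8, 6)
        assert m.precision == 0.75 and m.recall == 0.6
        assert m.iou == 0.5

    def test_iou_bounded_by_precision_and_recall(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            g = int(rng.integers(1, 50))
            p = int(rng.integers(1, 50))
            i = int(rng.integers(0, min(g, p) + 1))
            m = self._metrics(g, p, i)
            assert m.iou <= m.precision + 1e-12
            assert m.iou <= m.recall + 1e-12

    def test_vacuous_conventions(self):
        absent = self._metrics(0, 0, 0)
        assert absent.precision == 1.0 and absent.recall == 1.0
        assert absent.iou == 1.0
        missed = self._metrics(5, 0, 0)
        assert missed.precision == 0.0 and missed.recall == 0.0
        spurious = self._metrics(0, 5, 0)
        assert spurious.precision == 0.0 and spurious.recall == 0.0

    def test_macro_average_is_unweighted(self):
        per_image = [self._metrics(10, 10, 4, img="a"),   # IoU 0.25
                     self._metrics(10, 10, 6, img="b")]   # IoU 0.6/1.4
        table = macro_average(per_image)
        expected = np.mean([4 / 16, 6 / 14])
        assert table.loc["abnormal", "iou"] == pytest.approx(expected)

    def test_single_image_average_is_identity(self):
        m = self._metrics(10, 8, 6)
        table = macro_average([m])
        assert table.loc["abnormal", "precision"] == pytest.approx(m.precision)
        assert table.loc["abnormal", "iou"] == pytest.approx(m.iou)

    def test_mean_row_is_mean_of_class_means(self):
        per_image = [self._metrics(10, 10, 5, ClassLabel.ABNORMAL),
                     self._metrics(10, 10, 10, ClassLabel.NORMAL),
                     self._metrics(10, 10, 0, ClassLabel.OTHER)]
        table = macro_average(per_image)
        ious = [table.loc[c, "iou"] for c in ("abnormal", "normal", "other")]
        assert table.loc["mean", "iou"] == pytest.approx(np.mean(ious))

    def test_two_image_symmetry(self):
        per_image = [self._metrics(10, 10, 10 * 4 // 14, img="a"),
                     self._metrics(0, 0, 0, img="b")]
        table = macro_average(per_image)
        assert 0.0 <= table.loc["abnormal", "iou"] <= 1.0


class TestImageConfidence:
    def test_mean_over_predicted_points(self):
        labels = np.array([[1, 1], [0, 2]])
        probs = [[[0.1, 0.8, 0.1], [0.2, 0.6, 0.2]],
                 [[0.9, 0.05, 0.05], [0.1, 0.2, 0.7]]]
        pmap = _pointmap(labels, probs)
        assert image_confidence(pmap, ClassLabel.NORMAL) == pytest.approx(0.7)

    def test_no_points_of_class_gives_zero(self):
        labels = np.ones((2, 2), int)
        probs = [[[0.1, 0.8, 0.1]] * 2] * 2
        assert image_confidence(_pointmap(labels, probs),
                                ClassLabel.OTHER) == 0.0

    def test_all_points_mode(self):
        labels = np.array([[1, 0]])
        probs = [[[0.1, 0.8, 0.1], [0.6, 0.3, 0.1]]]
        pmap = _pointmap(labels, probs)
        assert image_confidence(pmap, ClassLabel.NORMAL, mode="all") \
            == pytest.approx(0.55)

    def test_ground_truth_map_rejected(self):
        with pytest.raises(ValueError):
            image_confidence(_pointmap(np.ones((2, 2), int)), ClassLabel.NORMAL)


def _ap_oracle(correct, n_gt):
    """Envelope AP by direct rank enumeration, independent of the
    implementation's vectorized cumulative form."""
    tp = fp = 0
    rows = []
    for c in correct:
        tp, fp = tp + int(c), fp + int(not c)
        rows.append((tp, tp / (tp + fp)))
    ap = 0.0
    for t in range(1, sum(correct) + 1):
        best = max(prec for cum_tp, prec in rows if cum_tp >= t)
        ap += best / n_gt
    return ap


class TestVocAp:
    def _dets(self, flags, confs=None):
        confs = confs or [0.9 - 0.1 * k for k in range(len(flags))]
        return [Detection(f"i{k}", c, 0.8 if f else 0.2)
                for k, (f, c) in enumerate(zip(flags, confs))]

    def test_all_correct_gives_one(self):
        res = voc_ap(self._dets([True] * 4), n_gt=4)
        assert res.ap == 1.0

    def test_all_incorrect_gives_zero(self):
        res = voc_ap(self._dets([False] * 4), n_gt=4)
        assert res.ap == 0.0

    def test_correct_incorrect_correct_walk(self):
        # ranked TP, FP, TP over 3 ground-truth instances:
        # envelope area = 1/3 * 1 + 1/3 * 2/3 = 5/9
        res = voc_ap(self._dets([True, False, True]), n_gt=3)
        assert res.ap == pytest.approx(5 / 9)
        assert res.ap == pytest.approx(_ap_oracle([True, False, True], 3))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_rank_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        flags = rng.random(n) < 0.6
        confs = np.round(rng.random(n), 3).tolist()
        n_gt = int(flags.sum() + rng.integers(0, 4))
        if n_gt == 0:
            n_gt = 1
        res = voc_ap(self._dets(flags.tolist(), confs), n_gt=n_gt)
        order = sorted(range(n), key=lambda k: (-confs[k], bool(flags[k])))
        assert res.ap == pytest.approx(
            _ap_oracle([bool(flags[k]) for k in order], n_gt))

    def test_invariant_to_permuting_tied_confidences(self):
        flags = [True, False, True, False]
        confs = [0.5, 0.5, 0.5, 0.9]
        base = voc_ap(self._dets(flags, confs), n_gt=3).ap
        for perm in itertools.permutations(range(3)):
            f = [flags[3]] + [flags[k] for k in perm]
            c = [confs[3]] + [confs[k] for k in perm]
            assert voc_ap(self._dets(f, c), n_gt=3).ap == pytest.approx(base)

    def test_eleven_point_variant_bounded(self):
        dets = self._dets([True, False, True, True], [0.9, 0.7, 0.6, 0.4])
        full = voc_ap(dets, n_gt=4, interpolation="all_point").ap
        eleven = voc_ap(dets, n_gt=4, interpolation="11point").ap
        assert 0.0 <= eleven <= 1.0 and 0.0 <= full <= 1.0

    def test_empty_detections_rejected(self):
        with pytest.raises(ValueError):
            voc_ap([], n_gt=1)


class TestEvaluatePointmaps:
    def test_full_pipeline_on_constructed_pairs(self):
        rng = np.random.default_rng(41)
        pairs = []
        for k in range(4):
            labels = rng.integers(0, 3, (6, 8))
            gt = _pointmap(labels, source=f"img{k}")
            noisy = labels.copy()
            flip = rng.random(labels.shape) < 0.15
            noisy[flip] = rng.integers(0, 3, int(flip.sum()))
            probs = np.zeros((6, 8, 3))
            for i in range(6):
                for j in range(8):
                    probs[i, j, noisy[i, j]] = 0.8
                    probs[i, j][probs[i, j] == 0] = 0.1
            pairs.append((gt, _pointmap(noisy, probs, source=f"img{k}")))
        per_image, table, aps = evaluate_pointmaps(pairs)
        assert len(per_image) == 12
        assert ((table[["precision", "recall", "f1", "iou"]] >= 0).all().all()
                and (table[["precision", "recall", "f1", "iou"]] <= 1).all().all())
        for res in aps.values():
            assert 0.0 <= res.ap <= 1.0
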