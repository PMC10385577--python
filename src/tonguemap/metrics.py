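"""Evaluation mathematics.

Two evaluation layers:

* **Patch classification** — a 3x3 confusion matrix (rows = actual,
  columns = predicted) from which one-vs-rest precision, recall, F1 and
  accuracy derive per class, plus rank-statistic ROC AUC.

* **Point-mapping segmentation** — per image and class, the point counts
  G (ground truth), P (prediction) and I (their intersection) give the
  union S = G + P - I and hence TP = I, FP = P - I, FN = G - I,
  IoU = I/S, precision = I/P and recall = I/G.  Per-image metrics are
  macro-averaged (unweighted over images, then over classes), and a
  PASCAL-VOC average precision treats each (image, class) region as one
  ground-truth instance: the prediction is a correct detection when its
  IoU reaches the 0.5 threshold, detections are ranked by the mean softmax
  confidence of the class, and AP is the area under the monotone
  precision envelope.

Note the TP/FP/FN assignment: a verbal reading of the segmentation-count
definitions that sets TP = P - I is internally inconsistent (it would make
TP equal FP); TP = I is the only assignment compatible with
precision = I/P and recall = I/G, and is what is implemented.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score as _sk_auc

from .dataset import CLASS_NAMES, ClassLabel, N_CLASSES
from .pointmap import PointMap


def round_report(x: float, places: int = 3) -> float:
    """Round half up, as the report tables do (e.g. 0.9655 -> 0.966)."""
    q = decimal.Decimal(10) ** -places
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


# --------------------------------------------------------------------------
# confusion-matrix metrics

@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 actual-by-predicted counts."""

    counts: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("confusion matrix must be 3x3")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", arr)

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionMatrix":
        return cls(_sk_confusion(y_true, y_pred, labels=range(N_CLASSES)))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(frame.to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.counts, index=CLASS_NAMES,
                     columns=CLASS_NAMES).to_csv(path)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def overall_accuracy(self) -> float:
        """trace / total — the plain multiclass accuracy."""
        return float(np.trace(self.counts) / self.total)

    def binary_counts(self, label: ClassLabel) -> tuple[int, int, int, int]:
        """One-vs-rest (TP, FP, FN, TN) for one class."""
        c = int(label)
        tp = int(self.counts[c, c])
        fp = int(self.counts[:, c].sum() - tp)
        fn = int(self.counts[c, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    accuracy: float
    auc: float | None = None
    flags: tuple[str, ...] = ()


def _safe_div(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(f"{name}: zero denominator, reported as 0")
        return 0.0
    return num / den


def class_metrics(cm: ConfusionMatrix, label: ClassLabel,
                  auc: float | None = None) -> ClassMetrics:
    """One-vs-rest precision, recall, F1 and accuracy for one class."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn, tn = cm.binary_counts(label)
    flags: list[str] = []
    precision = _safe_div(tp, tp + fp, flags, "precision")
    recall = _safe_div(tp, tp + fn, flags, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, flags, "f1")
    accuracy = (tp + tn) / cm.total
    return ClassMetrics(precision, recall, f1, accuracy, auc, tuple(flags))


def all_class_metrics(cm: ConfusionMatrix,
                      aucs: dict[ClassLabel, float] | None = None) -> pd.DataFrame:
    """Per-class metric table (one row per class, report layout)."""
    rows = []
    for label in ClassLabel:
        m = class_metrics(cm, label, (aucs or {}).get(label))
        rows.append({"class": label.name.lower(), "precision": m.precision,
                     "recall": m.recall, "f1": m.f1, "accuracy": m.accuracy,
                     "auc": m.auc})
    return pd.DataFrame(rows).set_index("class")


def roc_auc(y_true, scores, label: ClassLabel) -> float:
    """One-vs-rest AUC via the rank statistic (ties averaged)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores)
    pos = (y_true == int(label)).astype(int)
    if pos.all() or not pos.any():
        raise ValueError("AUC needs both positive and negative examples")
    s = scores[:, int(label)] if scores.ndim == 2 else scores
    return float(_sk_auc(pos, s))


# --------------------------------------------------------------------------
# point-count segmentation metrics

@dataclass(frozen=True)
class SegCounts:
    """G/P/I point counts for one class on one image, with derived terms."""

    label: ClassLabel
    g: int  # ground-truth points
    p: int  # predicted points
    i: int  # intersection points

    def __post_init__(self):
        if not (0 <= self.i <= min(self.g, self.p)):
            raise ValueError("intersection exceeds ground truth or prediction")

    @property
    def s(self) -> int:
        """Union count: S = G + P - I."""
        return self.g + self.p - self.i

    @property
    def tp(self) -> int:
        return self.i

    @property
    def fp(self) -> int:
        return self.p - self.i

    @property
    def fn(self) -> int:
        return self.g - self.i

    @property
    def iou(self) -> float:
        """I / S; both sets empty counts as perfect agreement (1.0)."""
        return self.i / self.s if self.s > 0 else 1.0


def seg_counts(gt: PointMap, pred: PointMap, label: ClassLabel) -> SegCounts:
    """Count G, P and I over the grid points of one class."""
    if (gt.grid.n_cols, gt.grid.n_rows) != (pred.grid.n_cols, pred.grid.n_rows):
        raise ValueError("point maps use different grids")
    if gt.image_shape != pred.image_shape:
        raise ValueError("point maps belong to different images")
    g_set = gt.class_points(label)
    p_set = pred.class_points(label)
    return SegCounts(label, len(g_set), len(p_set), len(g_set & p_set))


@dataclass(frozen=True)
class ImageSegMetrics:
    """Per-image, per-class segmentation metrics with the mean confidence."""

    image_id: str
    label: ClassLabel
    counts: SegCounts
    confidence: float
    flags: tuple[str, ...] = ()

    @property
    def precision(self) -> float:
        if self.counts.p == 0:
            return 1.0 if self.counts.g == 0 else 0.0  # vacuous when nothing exists
        return self.counts.i / self.counts.p

    @property
    def recall(self) -> float:
        if self.counts.g == 0:
            return 1.0 if self.counts.p == 0 else 0.0
        return self.counts.i / self.counts.g

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0

    @property
    def iou(self) -> float:
        return self.counts.iou


def image_confidence(pmap: PointMap, label: ClassLabel,
                     mode: str = "predicted") -> float:
    """Mean softmax probability of ``label`` over a point map.

    ``mode="predicted"`` (default) averages over the points predicted as
    that class — the confidence that ranks detections for AP — and returns
    0 when no point was predicted as the class.  ``mode="all"`` averages
    the class probability over every grid point.
    """
    probs = pmap.probs
    if probs is None:
        raise ValueError("point map carries no probabilities")
    if mode == "all":
        return float(probs[..., int(label)].mean())
    if mode != "predicted":
        raise ValueError("mode must be 'predicted' or 'all'")
    sel = pmap.labels == int(label)
    if not sel.any():
        return 0.0
    return float(probs[..., int(label)][sel].mean())


def evaluate_image(gt: PointMap, pred: PointMap, image_id: str = "",
                   confidence_mode: str = "predicted") -> list[ImageSegMetrics]:
    """All per-class segmentation metrics for one image."""
    out = []
    for label in ClassLabel:
        sc = seg_counts(gt, pred, label)
        conf = (image_confidence(pred, label, confidence_mode)
                if pred.probs is not None else float(sc.p > 0))
        flags = []
        if sc.p == 0:
            flags.append("no predicted points")
        if sc.g == 0:
            flags.append("no ground-truth points")
        out.append(ImageSegMetrics(image_id or pred.source_id, label, sc,
                                   conf, tuple(flags)))
    return out


def macro_average(per_image: Sequence[ImageSegMetrics]) -> pd.DataFrame:
    """Unweighted per-class means over images, plus a grand-mean row.

    The ``mean`` row is the unweighted mean of the three class means, not
    a pooled average over images.
    """
    if not per_image:
        raise ValueError("no per-image metrics to average")
    rows = {}
    for label in ClassLabel:
        ms = [m for m in per_image if m.label == label]
        if not ms:
            continue
        rows[label.name.lower()] = {
            "precision": float(np.mean([m.precision for m in ms])),
            "recall": float(np.mean([m.recall for m in ms])),
            "f1": float(np.mean([m.f1 for m in ms])),
            "iou": float(np.mean([m.iou for m in ms])),
            "n_images": len(ms),
        }
    frame = pd.DataFrame(rows).T
    mean_row = frame[["precision", "recall", "f1", "iou"]].mean(axis=0)
    frame.loc["mean", ["precision", "recall", "f1", "iou"]] = mean_row
    frame.loc["mean", "n_images"] = frame["n_images"].iloc[:-1].max()
    frame["n_images"] = frame["n_images"].astype(int)
    return frame


# --------------------------------------------------------------------------
# PASCAL-VOC average precision

@dataclass(frozen=True)
class Detection:
    """One per-image class detection: its confidence and whether IoU >= t."""

    image_id: str
    confidence: float
    iou: float


@dataclass(frozen=True)
class APResult:
    label: ClassLabel
    ap: float
    detections: tuple[Detection, ...]  # sorted by descending confidence
    precision: np.ndarray
    recall: np.ndarray
    n_gt: int


def _ap_all_point(recall: np.ndarray, precision: np.ndarray) -> float:
    """Area under the monotone (right-to-left max) precision envelope."""
    mrec = np.concatenate([[0.0], recall])
    mpre = np.concatenate([[0.0], precision])
    for k in range(len(mpre) - 2, -1, -1):
        mpre[k] = max(mpre[k], mpre[k + 1])
    return float(np.sum((mrec[1:] - mrec[:-1]) * mpre[1:]))


def _ap_11_point(recall: np.ndarray, precision: np.ndarray) -> float:
    levels = np.linspace(0.0, 1.0, 11)
    vals = []
    for r in levels:
        mask = recall >= r - 1e-12
        vals.append(float(precision[mask].max()) if mask.any() else 0.0)
    return float(np.mean(vals))


def voc_ap(detections: Iterable[Detection], n_gt: int,
           label: ClassLabel = ClassLabel.ABNORMAL,
           iou_threshold: float = 0.5,
           interpolation: str = "all_point") -> APResult:
    """Average precision over per-image class detections.

    Each image contributes at most one detection per class (its predicted
    point set) and one ground-truth instance when the class is present.
    A detection is correct when its IoU meets ``iou_threshold``.
    Detections are ranked by descending confidence; at equal confidence,
    incorrect detections rank before correct ones (a pessimistic,
    permutation-invariant tie rule).  ``interpolation`` selects the
    all-point monotone envelope (default) or the 11-point variant.
    """
    dets = list(detections)
    if not dets:
        raise ValueError("no detections")
    if n_gt < 0:
        raise ValueError("n_gt must be non-negative")
    correct = [d.iou >= iou_threshold for d in dets]
    order = sorted(range(len(dets)),
                   key=lambda k: (-dets[k].confidence, correct[k]))
    dets = [dets[k] for k in order]
    correct_arr = np.array([correct[k] for k in order], dtype=bool)
    tp = np.cumsum(correct_arr)
    fp = np.cumsum(~correct_arr)
    precision = tp / np.maximum(tp + fp, 1)
    recall = tp / n_gt if n_gt > 0 else np.ones_like(tp, dtype=float)
    if interpolation == "all_point":
        ap = _ap_all_point(recall, precision)
    elif interpolation == "11point":
        ap = _ap_11_point(recall, precision)
    else:
        raise ValueError("interpolation must be 'all_point' or '11point'")
    return APResult(label, ap, tuple(dets), precision, recall, n_gt)


def evaluate_pointmaps(pairs: Sequence[tuple[PointMap, PointMap]],
                       iou_threshold: float = 0.5,
                       interpolation: str = "all_point",
                       confidence_mode: str = "predicted",
                       ) -> tuple[list[ImageSegMetrics], pd.DataFrame,
                                  dict[ClassLabel, APResult]]:
    """Full segmentation evaluation over (ground-truth, predicted) pairs.

    Returns per-image metrics, the macro-average table and per-class AP.
    Classes absent from every image (no ground truth and no prediction)
    get no AP entry.
    """
    per_image: list[ImageSegMetrics] = []
    for gt, pred in pairs:
        per_image.extend(evaluate_image(gt, pred,
                                        confidence_mode=confidence_mode))
    table = macro_average(per_image)
    aps: dict[ClassLabel, APResult] = {}
    for label in ClassLabel:
        ms = [m for m in per_image if m.label == label]
        dets = [Detection(m.image_id, m.confidence, m.iou)
                for m in ms if m.counts.p > 0]
        n_gt = sum(1 for m in ms if m.counts.g > 0)
        if dets:
            aps[label] = voc_ap(dets, n_gt, label, iou_threshold, interpolation)
    return per_image, table, aps
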