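"""Detection and classification evaluation metrics.

IoU, greedy detection-truth matching, precision/recall/F1, accuracy,
PR curves with AP (all-point interpolated envelope by default, 11-point by
flag), mAP, confusion matrices, and mIoU.  F1 is the harmonic mean of
precision and recall.  Report values are displayed rounded half-up to three
decimals.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

from .hypercube import BoundingBox


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding (0.0005 -> 0.001 at ndigits=3)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two half-open pixel boxes; 0 when disjoint."""
    ix = max(0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


@dataclass
class MatchCounts:
    """TP/FP/FN/TN tallies; P and N are the positive/negative totals."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


def _det_fields(d):
    """Accept Detection-like objects or (box, label, confidence) tuples."""
    if hasattr(d, "box"):
        return d.box, d.label, d.confidence
    return d[0], d[1], d[2]


def match_detections(
    preds: Sequence, truths: Sequence[tuple[str, BoundingBox]], iou_threshold: float = 0.5
) -> tuple[MatchCounts, list[tuple[int, int | None, float]]]:
    """Greedy confidence-ordered matching of predictions to truths.

    Each prediction (highest confidence first) matches the highest-IoU
    unmatched truth of its class at IoU >= threshold (TP), otherwise it is an
    FP.  Unmatched truths are FN.  Returns counts plus an assignment list of
    (pred index, matched truth index or None, IoU).
    """
    order = sorted(
        range(len(preds)), key=lambda i: (-_det_fields(preds[i])[2], i)
    )
    matched_truth: set[int] = set()
    assignment: list[tuple[int, int | None, float]] = [None] * len(preds)  # type: ignore
    tp = fp = 0
    for i in order:
        box, label, _conf = _det_fields(preds[i])
        best_j, best_iou = None, 0.0
        for j, (t_label, t_box) in enumerate(truths):
            if j in matched_truth or t_label != label:
                continue
            v = iou(box, t_box)
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        if best_j is None:
            fp += 1
            assignment[i] = (i, None, 0.0)
        else:
            tp += 1
            matched_truth.add(best_j)
            assignment[i] = (i, best_j, best_iou)
    fn = len(truths) - len(matched_truth)
    return MatchCounts(tp=tp, fp=fp, fn=fn), assignment


def precision_recall_f1(c: MatchCounts) -> tuple[float, float, float]:
    """precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R).

    Degenerate denominators yield 0 with a warning.
    """
    if c.tp + c.fp == 0:
        warnings.warn("no predicted positives; precision defined as 0")
        precision = 0.0
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        warnings.warn("no actual positives; recall defined as 0")
        recall = 0.0
    else:
        recall = c.tp / (c.tp + c.fn)
    return precision, recall, f1_from_precision_recall(precision, recall)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def accuracy(c: MatchCounts) -> float:
    """(TP + TN) / (P + N)."""
    if c.p + c.n == 0:
        raise ValueError("accuracy undefined: P + N = 0")
    return (c.tp + c.tn) / (c.p + c.n)


@dataclass
class PRCurve:
    """Recall/precision points swept over confidence, for one class."""

    recalls: np.ndarray
    precisions: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.recalls = np.asarray(self.recalls, dtype=float)
        self.precisions = np.asarray(self.precisions, dtype=float)
        if np.any(np.diff(self.recalls) < 0):
            raise ValueError("recalls must be non-decreasing")


def pr_curve_and_ap(
    preds_by_image: Mapping[object, Sequence],
    truths_by_image: Mapping[object, Sequence[tuple[str, BoundingBox]]],
    class_label: str,
    iou_threshold: float = 0.5,
    interpolation: str = "all",
) -> tuple[PRCurve, float | None]:
    """PR curve and AP for one class over a collection of images.

    Predictions of the class are pooled across images and sorted by
    confidence; each is a TP if it matches an unmatched truth of the class in
    its image at IoU >= threshold.  AP integrates the monotone precision
    envelope over recall ("all"-point interpolation) or averages precision at
    the 11 canonical recall levels (``interpolation="11point"``).

    Returns (curve, AP); AP is None with a warning when the class has no
    ground-truth instances.
    """
    if interpolation not in ("all", "11point"):
        raise ValueError(f"unknown interpolation '{interpolation}'")
    flat: list[tuple[float, object, BoundingBox]] = []
    for img, preds in preds_by_image.items():
        for d in preds:
            box, label, conf = _det_fields(d)
            if label == class_label:
                flat.append((conf, img, box))
    truth_boxes = {
        img: [b for lbl, b in truths if lbl == class_label]
        for img, truths in truths_by_image.items()
    }
    n_truth = sum(len(v) for v in truth_boxes.values())
    if n_truth == 0:
        warnings.warn(f"no ground truth for class '{class_label}'; AP undefined")
        return PRCurve(np.array([]), np.array([]), class_label), None

    flat.sort(key=lambda t: (-t[0], str(t[1])))
    matched: dict[object, set[int]] = {img: set() for img in truths_by_image}
    tps = np.zeros(len(flat))
    for k, (_conf, img, box) in enumerate(flat):
        best_j, best_iou = None, 0.0
        for j, t_box in enumerate(truth_boxes.get(img, [])):
            if j in matched.get(img, set()):
                continue
            v = iou(box, t_box)
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        if best_j is not None:
            tps[k] = 1.0
            matched.setdefault(img, set()).add(best_j)
    cum_tp = np.cumsum(tps)
    cum_fp = np.cumsum(1.0 - tps)
    recalls = cum_tp / n_truth
    precisions = cum_tp / np.maximum(cum_tp + cum_fp, 1)
    curve = PRCurve(recalls, precisions, class_label)

    if len(flat) == 0:
        return curve, 0.0
    # monotone non-increasing precision envelope
    mrec = np.concatenate([[0.0], recalls, [recalls[-1]]])
    mpre = np.concatenate([[0.0], precisions, [0.0]])
    for i in range(mpre.size - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    if interpolation == "all":
        ap = float(np.sum((mrec[1:] - mrec[:-1]) * mpre[1:]))
    else:
        levels = np.linspace(0.0, 1.0, 11)
        vals = [mpre[np.searchsorted(mrec, lv, side="left")] if lv <= mrec[-1] else 0.0 for lv in levels]
        ap = float(np.mean(vals))
    return curve, ap


def mean_ap(aps: Iterable[float]) -> float:
    """Arithmetic mean of per-class AP values."""
    aps = [float(a) for a in aps]
    if not aps:
        raise ValueError("mean AP of an empty list is undefined")
    return float(np.mean(aps))


def confusion_matrix(
    y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str]
) -> np.ndarray:
    """Rows = true class, columns = predicted class."""
    if len(y_true) != len(y_pred):
        raise ValueError("label lists must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    m = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in ({t!r}, {p!r})")
        m[index[t], index[p]] += 1
    return m


def mean_iou(ious_by_image: Sequence[Sequence[float]], per_image: bool = True) -> float:
    """Mean matched-pair IoU, averaged per image then across images.

    With ``per_image=False`` the global mean over all matched pairs is
    returned instead.  Returns NaN with a warning when there are no matches.
    """
    groups = [np.asarray(g, dtype=float) for g in ious_by_image if len(g)]
    if not groups:
        warnings.warn("no matched detections; mIoU undefined")
        return float("nan")
    if per_image:
        return float(np.mean([g.mean() for g in groups]))
    return float(np.concatenate(groups).mean())


@dataclass
class EvaluationReport:
    """Per-class and aggregate detection metrics (the report table)."""

    classes: list[str]
    per_class: dict[str, dict[str, float | None]]
    miou: float
    map: float | None
    confusion: np.ndarray

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "per_class": self.per_class,
            "mIoU": self.miou,
            "mAP": self.map,
            "confusion": self.confusion.tolist(),
        }

    def to_table(self) -> str:
        cols = ["Precision", "Recall", "F1 Score", "AP", "IoU"]
        lines = ["Label\t" + "\t".join(cols + ["mIoU", "mAP"])]
        for i, c in enumerate(self.classes):
            row = self.per_class[c]
            cells = [
                _fmt(row["precision"]),
                _fmt(row["recall"]),
                _fmt(row["f1"]),
                _fmt(row["ap"]),
                _fmt(row["iou"]),
            ]
            if i == 0:
                cells += [_fmt(self.miou), _fmt(self.map)]
            lines.append(c + "\t" + "\t".join(cells))
        return "\n".join(lines)


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "-"
    return f"{round_half_up(x, 3):.3f}"


def evaluate_detections(
    preds_by_image: Mapping[object, Sequence],
    truths_by_image: Mapping[object, Sequence[tuple[str, BoundingBox]]],
    classes: Sequence[str],
    iou_threshold: float = 0.5,
    conf_threshold: float = 0.5,
    interpolation: str = "all",
) -> EvaluationReport:
    """Full report: P/R/F1 and IoU at the confidence threshold, AP over all
    confidences, per-image mIoU, mAP, and a matched-pair confusion matrix.

    The confusion matrix pairs class-agnostically matched detections with
    their truths, so cross-class mistakes are visible.
    """
    classes = list(classes)
    per_class: dict[str, dict[str, float | None]] = {}
    aps = []
    conf_true: list[str] = []
    conf_pred: list[str] = []
    ious_by_image: list[list[float]] = []

    thresholded = {
        img: [d for d in preds if _det_fields(d)[2] >= conf_threshold]
        for img, preds in preds_by_image.items()
    }

    for c in classes:
        counts = MatchCounts()
        class_ious: list[float] = []
        for img, truths in truths_by_image.items():
            preds_c = [d for d in thresholded.get(img, []) if _det_fields(d)[1] == c]
            truths_c = [t for t in truths if t[0] == c]
            mc, assignment = match_detections(preds_c, truths_c, iou_threshold)
            counts = counts + mc
            class_ious.extend(v for _, j, v in assignment if j is not None)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            precision, recall, f1 = precision_recall_f1(counts)
        _curve, ap = pr_curve_and_ap(
            preds_by_image, truths_by_image, c, iou_threshold, interpolation
        )
        if ap is not None:
            aps.append(ap)
        per_class[c] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "ap": ap,
            "iou": float(np.mean(class_ious)) if class_ious else None,
            "tp": counts.tp,
            "fp": counts.fp,
            "fn": counts.fn,
        }

    # class-agnostic matching for mIoU and the confusion matrix
    for img, truths in truths_by_image.items():
        preds = thresholded.get(img, [])
        order = sorted(range(len(preds)), key=lambda i: (-_det_fields(preds[i])[2], i))
        used: set[int] = set()
        img_ious: list[float] = []
        for i in order:
            box, label, _ = _det_fields(preds[i])
            best_j, best_iou = None, 0.0
            for j, (_t_label, t_box) in enumerate(truths):
                if j in used:
                    continue
                v = iou(box, t_box)
                if v >= iou_threshold and v > best_iou:
                    best_j, best_iou = j, v
            if best_j is not None:
                used.add(best_j)
                img_ious.append(best_iou)
                conf_true.append(truths[best_j][0])
                conf_pred.append(label)
        ious_by_image.append(img_ious)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        miou = mean_iou(ious_by_image)
    return EvaluationReport(
        classes=classes,
        per_class=per_class,
        miou=miou,
        map=mean_ap(aps) if aps else None,
        confusion=confusion_matrix(conf_true, conf_pred, classes),
    )
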