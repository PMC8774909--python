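"""Instance-segmentation metrics: mean precision, mean recall, mean IOU.

Predicted and ground-truth instance masks are matched greedily one-to-one at
an IOU threshold (default 0.5): predictions are visited in descending score
order (ties and missing scores: descending best IOU, then index) and each
claims its highest-IOU unclaimed ground truth.  TP/FP/FN then give precision
and recall; mean IOU averages matched pairs only, so unmatched instances are
reflected in precision/recall rather than diluting the IOU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AnnotationError


@dataclass
class InstanceSet:
    """Binary instance masks over one image frame, with optional confidences."""

    masks: list
    scores: list | None = None

    def __post_init__(self) -> None:
        self.masks = [np.asarray(m, dtype=bool) for m in self.masks]
        shapes = {m.shape for m in self.masks}
        if len(shapes) > 1:
            raise AnnotationError(f"masks have mixed shapes: {shapes}")
        if self.scores is not None:
            if len(self.scores) != len(self.masks):
                raise AnnotationError("scores do not align 1:1 with masks")
            self.scores = [float(s) for s in self.scores]
            if any(not (0.0 <= s <= 1.0) for s in self.scores):
                raise AnnotationError("scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.masks)


@dataclass
class MatchResult:
    pairs: list            # (pred index, gt index, iou)
    unmatched_preds: list
    unmatched_gts: list


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two boolean masks (0 when both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise AnnotationError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def match_instances(
    preds: InstanceSet, gts: InstanceSet, iou_threshold: float = 0.5
) -> MatchResult:
    """Greedy one-to-one matching of predictions to ground truths."""
    n_pred, n_gt = len(preds), len(gts)
    iou = np.zeros((n_pred, n_gt))
    for i in range(n_pred):
        for j in range(n_gt):
            iou[i, j] = mask_iou(preds.masks[i], gts.masks[j])

    best = iou.max(axis=1) if n_gt else np.zeros(n_pred)
    if preds.scores is not None:
        order = sorted(range(n_pred), key=lambda i: (-preds.scores[i], -best[i], i))
    else:
        order = sorted(range(n_pred), key=lambda i: (-best[i], i))

    claimed = np.zeros(n_gt, dtype=bool)
    pairs = []
    unmatched_preds = []
    for i in order:
        j_best, v_best = -1, -1.0
        for j in range(n_gt):
            if not claimed[j] and iou[i, j] > v_best:
                j_best, v_best = j, iou[i, j]
        if j_best >= 0 and v_best >= iou_threshold:
            claimed[j_best] = True
            pairs.append((i, j_best, float(v_best)))
        else:
            unmatched_preds.append(i)
    unmatched_gts = [j for j in range(n_gt) if not claimed[j]]
    return MatchResult(pairs=pairs, unmatched_preds=sorted(unmatched_preds),
                       unmatched_gts=unmatched_gts)


@dataclass
class ImageEval:
    """Per-image evaluation with the counts needed for pooled aggregation."""

    tp: int
    fp: int
    fn: int
    matched_ious: list
    precision: float
    recall: float
    mean_iou: float


def _ratio(num: int, den: int, empty_value: float) -> float:
    return num / den if den else empty_value


def segmentation_metrics(
    preds: InstanceSet, gts: InstanceSet, iou_threshold: float = 0.5
):
    """Return ``(precision, recall, mean_iou)`` for one image.

    Conventions for empty inputs: with zero predictions, precision is 1.0 if
    there are also zero ground truths and 0.0 otherwise (and symmetrically for
    recall); mean IOU is 0.0 when no pair matched.
    """
    ev = evaluate_image(preds, gts, iou_threshold)
    return ev.precision, ev.recall, ev.mean_iou


def evaluate_image(
    preds: InstanceSet, gts: InstanceSet, iou_threshold: float = 0.5
) -> ImageEval:
    match = match_instances(preds, gts, iou_threshold)
    tp = len(match.pairs)
    fp = len(match.unmatched_preds)
    fn = len(match.unmatched_gts)
    matched_ious = [v for _, _, v in match.pairs]
    precision = _ratio(tp, tp + fp, 1.0 if fn == 0 else 0.0)
    recall = _ratio(tp, tp + fn, 1.0 if fp == 0 else 0.0)
    mean_iou = float(np.mean(matched_ious)) if matched_ious else 0.0
    return ImageEval(tp, fp, fn, matched_ious, precision, recall, mean_iou)


def dataset_metrics(per_image: list, aggregation: str = "macro"):
    """Aggregate :class:`ImageEval` results over a dataset.

    ``macro`` (default) is the unweighted mean of per-image metrics; ``micro``
    pools TP/FP/FN and matched IOUs across images first.
    """
    if not per_image:
        raise AnnotationError("dataset_metrics needs at least one image")
    if aggregation == "macro":
        precision = float(np.mean([e.precision for e in per_image]))
        recall = float(np.mean([e.recall for e in per_image]))
        mean_iou = float(np.mean([e.mean_iou for e in per_image]))
        return precision, recall, mean_iou
    if aggregation == "micro":
        tp = sum(e.tp for e in per_image)
        fp = sum(e.fp for e in per_image)
        fn = sum(e.fn for e in per_image)
        ious = [v for e in per_image for v in e.matched_ious]
        precision = _ratio(tp, tp + fp, 1.0 if fn == 0 else 0.0)
        recall = _ratio(tp, tp + fn, 1.0 if fp == 0 else 0.0)
        mean_iou = float(np.mean(ious)) if ious else 0.0
        return precision, recall, mean_iou
    raise ValueError(f"unknown aggregation {aggregation!r}")
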