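"""Detection metrics and the continual-domain experiment report.

Implements Precision / Recall at a fixed confidence operating point,
COCO-style mean average precision (101-point interpolated PR
integration, averaged over classes then over IoU thresholds: 0.5 for
mAP50, 0.50:0.05:0.95 for mAP50-95), a (K+1)-way confusion matrix with a
background row/column, and the per-domain report used by the continual
test-time adaptation experiment.

Predictions are per-image dicts with ``boxes`` (P,4), ``scores`` (P,)
and ``classes`` (P,) — the output format of
:func:`cdpd.mtdam.nms_detections`.  Matching is greedy by IoU within a
class, in descending score order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .mtdam import iou_matrix
from .synthetic_scenes import LabeledScene

__all__ = [
    "MetricSet", "DomainSequenceResult", "precision_recall",
    "average_precision", "mean_average_precision", "confusion_matrix",
    "evaluate_detections", "run_domain_sequence_report", "render_table",
    "MAP5095_THRESHOLDS",
]

MAP5095_THRESHOLDS = tuple(np.arange(0.5, 0.96, 0.05).round(2))
DEFAULT_CONF_THRESH = 0.25  # Precision/Recall operating point


@dataclass(frozen=True)
class MetricSet:
    precision: float
    recall: float
    map50: float
    map50_95: float

    def __post_init__(self):
        for name in ("precision", "recall", "map50", "map50_95"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_dict(self) -> dict:
        return {"precision": self.precision, "recall": self.recall,
                "map50": self.map50, "map50_95": self.map50_95}


@dataclass
class DomainSequenceResult:
    domains: list[str]
    per_domain: dict[str, MetricSet]
    average: MetricSet

    def as_dict(self) -> dict:
        return {"domains": list(self.domains),
                "per_domain": {d: m.as_dict() for d, m in self.per_domain.items()},
                "average": self.average.as_dict()}


def _match_greedy_by_score(pred_boxes, pred_scores, gt_boxes, iou_thresh):
    """Greedily match predictions (descending score) to unmatched truths.
    Returns a boolean TP flag per prediction (in the given order)."""
    matched_gt: set[int] = set()
    tp = np.zeros(len(pred_boxes), dtype=bool)
    if len(gt_boxes) and len(pred_boxes):
        mat = iou_matrix(pred_boxes, gt_boxes)
        order = np.argsort(-np.asarray(pred_scores), kind="stable")
        for p in order:
            best_t, best_iou = -1, iou_thresh
            for t in range(len(gt_boxes)):
                if t in matched_gt:
                    continue
                if mat[p, t] >= best_iou:
                    best_t, best_iou = t, mat[p, t]
            if best_t >= 0:
                matched_gt.add(best_t)
                tp[p] = True
    return tp


def precision_recall(preds: list[dict], truths: list[LabeledScene],
                     iou_thresh: float = 0.5,
                     conf_thresh: float = DEFAULT_CONF_THRESH
                     ) -> tuple[float, float]:
    """TP/(TP+FP) and TP/(TP+FN) at a confidence threshold.

    Matching is class-aware and greedy by score within each image.
    Precision is 0 by convention when there are no predictions.
    """
    tp = fp = n_truth = 0
    for pred, truth in zip(preds, truths):
        keep = np.asarray(pred["scores"]) >= conf_thresh
        boxes = np.asarray(pred["boxes"]).reshape(-1, 4)[keep]
        scores = np.asarray(pred["scores"])[keep]
        classes = np.asarray(pred["classes"])[keep]
        n_truth += len(truth.boxes)
        for c in np.unique(classes):
            sel = classes == c
            gt_sel = truth.class_ids == c
            flags = _match_greedy_by_score(boxes[sel], scores[sel],
                                           truth.boxes[gt_sel], iou_thresh)
            tp += int(flags.sum())
            fp += int((~flags).sum())
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / n_truth if n_truth > 0 else 0.0
    return precision, recall


def average_precision(preds: list[dict], truths: list[LabeledScene],
                      class_id: int, iou_thresh: float) -> float | None:
    """101-point interpolated AP for one class; None if the class is
    absent from the truths (excluded from the mean)."""
    n_gt = sum(int((t.class_ids == class_id).sum()) for t in truths)
    if n_gt == 0:
        return None

    rows = []  # (score, tp) over all images
    for img_i, (pred, truth) in enumerate(zip(preds, truths)):
        classes = np.asarray(pred["classes"])
        sel = classes == class_id
        boxes = np.asarray(pred["boxes"]).reshape(-1, 4)[sel]
        scores = np.asarray(pred["scores"])[sel]
        gt_boxes = truth.boxes[truth.class_ids == class_id]
        flags = _match_greedy_by_score(boxes, scores, gt_boxes, iou_thresh)
        rows.extend(zip(scores, flags))
    if not rows:
        return 0.0
    rows.sort(key=lambda r: -r[0])
    tps = np.cumsum([f for _, f in rows])
    fps = np.cumsum([not f for _, f in rows])
    recalls = tps / n_gt
    precisions = tps / (tps + fps)
    # 101-point interpolation: max precision at recall >= r
    ap = 0.0
    for r in np.linspace(0.0, 1.0, 101):
        mask = recalls >= r - 1e-12
        ap += precisions[mask].max() if mask.any() else 0.0
    return ap / 101.0


def mean_average_precision(preds: list[dict], truths: list[LabeledScene],
                           iou_thresholds=(0.5,)) -> float:
    """Per-class AP averaged over classes present in the truths, then
    over IoU thresholds."""
    present = sorted({int(c) for t in truths for c in t.class_ids})
    if not present:
        return 0.0
    per_thresh = []
    for thr in iou_thresholds:
        aps = [average_precision(preds, truths, c, thr) for c in present]
        aps = [a for a in aps if a is not None]
        per_thresh.append(float(np.mean(aps)) if aps else 0.0)
    return float(np.mean(per_thresh))


def confusion_matrix(preds: list[dict], truths: list[LabeledScene],
                     iou_thresh: float = 0.5, num_classes: int | None = None,
                     conf_thresh: float = DEFAULT_CONF_THRESH) -> np.ndarray:
    """(K+1) x (K+1) counts indexed [true, predicted]; index K is
    background (unmatched truths in the background column, unmatched
    predictions in the background row).  Matching here is class-agnostic
    so cross-class confusions are visible."""
    if num_classes is None:
        num_classes = 1 + max((int(c) for t in truths for c in t.class_ids),
                              default=0)
    k = num_classes
    mat = np.zeros((k + 1, k + 1), dtype=int)
    for pred, truth in zip(preds, truths):
        keep = np.asarray(pred["scores"]) >= conf_thresh
        boxes = np.asarray(pred["boxes"]).reshape(-1, 4)[keep]
        scores = np.asarray(pred["scores"])[keep]
        classes = np.asarray(pred["classes"])[keep]
        matched_t: set[int] = set()
        matched_p: set[int] = set()
        if len(boxes) and len(truth.boxes):
            m = iou_matrix(boxes, truth.boxes)
            for p in np.argsort(-scores, kind="stable"):
                best_t, best_iou = -1, iou_thresh
                for t in range(len(truth.boxes)):
                    if t in matched_t:
                        continue
                    if m[p, t] >= best_iou:
                        best_t, best_iou = t, m[p, t]
                if best_t >= 0:
                    matched_t.add(best_t)
                    matched_p.add(int(p))
                    mat[int(truth.class_ids[best_t]), int(classes[p])] += 1
        for t in range(len(truth.boxes)):
            if t not in matched_t:
                mat[int(truth.class_ids[t]), k] += 1
        for p in range(len(boxes)):
            if p not in matched_p:
                mat[k, int(classes[p])] += 1
    return mat


def evaluate_detections(preds: list[dict], truths: list[LabeledScene],
                        conf_thresh: float = DEFAULT_CONF_THRESH) -> MetricSet:
    p, r = precision_recall(preds, truths, 0.5, conf_thresh)
    return MetricSet(
        precision=p, recall=r,
        map50=mean_average_precision(preds, truths, (0.5,)),
        map50_95=mean_average_precision(preds, truths, MAP5095_THRESHOLDS))


# ---------------------------------------------------------------------------
# continual-domain report
# ---------------------------------------------------------------------------

def _mean_metrics(values: list[MetricSet]) -> MetricSet:
    return MetricSet(
        precision=float(np.mean([m.precision for m in values])),
        recall=float(np.mean([m.recall for m in values])),
        map50=float(np.mean([m.map50 for m in values])),
        map50_95=float(np.mean([m.map50_95 for m in values])))


def sequence_result(domains: list[str],
                    per_domain: dict[str, MetricSet]) -> DomainSequenceResult:
    return DomainSequenceResult(
        domains=list(domains), per_domain=dict(per_domain),
        average=_mean_metrics([per_domain[d] for d in domains]))


def run_domain_sequence_report(strategies: dict, stream: list[tuple[str, list]],
                               out_path=None) -> dict[str, DomainSequenceResult]:
    """Evaluate named adaptation strategies over an ordered domain stream.

    Each strategy is a callable ``stream -> {domain: [per-image pred dict]}``
    run on its own copy of the stream (domains processed in order, state
    carrying over inside the strategy).  Emits a JSON report and a rendered
    text table when ``out_path`` is given.
    """
    domains = [d for d, _ in stream]
    results: dict[str, DomainSequenceResult] = {}
    for name, strategy in strategies.items():
        preds_by_domain = strategy(stream)
        per_domain = {}
        for domain, scenes in stream:
            per_domain[domain] = evaluate_detections(
                preds_by_domain[domain], scenes)
        results[name] = sequence_result(domains, per_domain)
    if out_path is not None:
        from pathlib import Path
        path = Path(out_path)
        path.write_text(json.dumps(
            {name: r.as_dict() for name, r in results.items()}, indent=1))
        path.with_suffix(".txt").write_text(render_table(results))
    return results


def render_table(results: dict[str, DomainSequenceResult]) -> str:
    """Text table of per-domain mAP50 with the running average column."""
    domains = next(iter(results.values())).domains
    header = ["method"] + domains + ["Avg"]
    lines = ["  ".join(f"{h:>8s}" for h in header)]
    for name, res in results.items():
        cells = [f"{res.per_domain[d].map50:8.3f}" for d in domains]
        cells.append(f"{res.average.map50:8.3f}")
        lines.append("  ".join([f"{name:>8s}"] + cells))
    return "\n".join(lines) + "\n"
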