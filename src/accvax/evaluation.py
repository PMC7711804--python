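"""Validation statistics: confusion outcomes, ROC/PR metrics, cross-validation.

The eight statistics reported for each immunogenicity model: sensitivity
(recall), specificity, accuracy, precision, area under the ROC curve (AROC),
area under the precision-recall curve (APR), Matthews correlation
coefficient (MCC) and F1.  Cross-validation is stratified and seeded, with
feature selection and scaling redone inside every fold, and metrics are
computed from the pooled out-of-fold predictions (the summary convention of
classical data-mining toolkits) rather than averaged across folds.

Zero-denominator conventions (documented and test-pinned): precision is 0
when nothing is predicted positive, MCC is 0 when any factor of its
denominator is 0, F1 is 0 when precision + recall is 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .data import LabeledDataset
from .models import ModelConfig, predict_scores, train_model

__all__ = [
    "ConfusionCounts",
    "ClassificationMetrics",
    "confusion_counts",
    "compute_metrics",
    "cross_validate",
    "roc_points",
    "pr_points",
    "metrics_to_tsv_row",
    "metrics_to_json",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """The four binary-classification outcomes."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"confusion count {name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class ClassificationMetrics:
    """The eight validation statistics for one model on one record set.

    ``aroc`` and ``apr`` are None when no continuous scores were supplied.
    """

    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    mcc: float
    f1: float
    aroc: float | None
    apr: float | None
    counts: ConfusionCounts


def _check_binary(values: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return arr.astype(int)


def confusion_counts(true_labels: np.ndarray, predicted_labels: np.ndarray) -> ConfusionCounts:
    """Count TP/TN/FP/FN with class 1 = immunogen as the positive class."""
    y = _check_binary(true_labels, "true_labels")
    p = _check_binary(predicted_labels, "predicted_labels")
    if y.shape != p.shape:
        raise ValueError(
            f"label vectors disagree in length: {y.shape} vs {p.shape}")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def compute_metrics(counts: ConfusionCounts,
                    scores: np.ndarray | None = None,
                    true_labels: np.ndarray | None = None) -> ClassificationMetrics:
    """All eight statistics from confusion counts and (optionally) scores.

    AROC is the trapezoidal area under the ROC curve swept over all score
    thresholds (tied scores form a single operating point); APR is the
    step-wise precision-recall summation.  Both require ``scores`` together
    with ``true_labels`` and are left as None otherwise.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    pos, neg = tp + fn, tn + fp

    sensitivity = tp / pos if pos else 0.0
    specificity = tn / neg if neg else 0.0
    accuracy = (tp + tn) / counts.total if counts.total else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0

    denom_factors = (tp + fp, tp + fn, tn + fp, tn + fn)
    if any(factor == 0 for factor in denom_factors):
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / float(np.sqrt(np.prod(np.array(denom_factors, dtype=float))))

    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if (precision + sensitivity) > 0 else 0.0)

    aroc = apr = None
    if scores is not None:
        if true_labels is None:
            raise ValueError("aroc/apr need both scores and true_labels")
        y = _check_binary(true_labels, "true_labels")
        s = np.asarray(scores, dtype=float)
        if y.shape != s.shape:
            raise ValueError("scores and true_labels disagree in length")
        if len(np.unique(y)) < 2:
            raise ValueError("aroc/apr require both classes among true_labels")
        aroc = float(roc_auc_score(y, s))
        apr = float(average_precision_score(y, s))

    return ClassificationMetrics(
        sensitivity=sensitivity, specificity=specificity, accuracy=accuracy,
        precision=precision, mcc=float(mcc), f1=f1, aroc=aroc, apr=apr,
        counts=counts,
    )


def evaluate_predictions(true_labels: np.ndarray, predicted_labels: np.ndarray,
                         scores: np.ndarray | None = None) -> ClassificationMetrics:
    """Convenience wrapper: confusion counts plus metrics in one call."""
    counts = confusion_counts(true_labels, predicted_labels)
    return compute_metrics(counts, scores=scores, true_labels=true_labels)


def cross_validate(config: ModelConfig, dataset: LabeledDataset,
                   k_folds: int = 10, seed: int = 0,
                   ) -> tuple[ClassificationMetrics, list[dict[str, Any]]]:
    """Stratified k-fold cross-validation with leakage-free refitting.

    Fold assignment is stratified and driven by ``seed``.  Inside each fold
    the model is trained from scratch on the training part only — including
    feature selection and standardization — and scores the held-out part.
    The pooled out-of-fold predictions yield one confusion table and one set
    of metrics; per-fold detail (indices, counts, accuracy) is returned
    alongside.
    """
    if dataset.labels is None:
        raise ValueError("cross-validation requires a labeled dataset")
    class_counts = np.bincount(dataset.labels, minlength=2)
    if (class_counts < k_folds).any():
        raise ValueError(
            f"each class needs at least k_folds={k_folds} records; "
            f"class counts are {class_counts.tolist()}")

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    n = dataset.n_records
    pooled_scores = np.empty(n, dtype=float)
    pooled_labels = np.empty(n, dtype=int)
    fold_detail: list[dict[str, Any]] = []
    for fold_index, (train_idx, test_idx) in enumerate(skf.split(dataset.features, dataset.labels)):
        model = train_model(config, dataset.subset(train_idx))
        scores, labels = predict_scores(model, dataset.features[test_idx])
        pooled_scores[test_idx] = scores
        pooled_labels[test_idx] = labels
        fold_counts = confusion_counts(dataset.labels[test_idx], labels)
        fold_detail.append({
            "fold": fold_index,
            "test_indices": test_idx.tolist(),
            "counts": fold_counts,
            "accuracy": (fold_counts.tp + fold_counts.tn) / fold_counts.total,
        })

    counts = confusion_counts(dataset.labels, pooled_labels)
    metrics = compute_metrics(counts, scores=pooled_scores, true_labels=dataset.labels)
    return metrics, fold_detail


# ---------------------------------------------------------------------------
# Curve points and export
# ---------------------------------------------------------------------------

def roc_points(true_labels: np.ndarray, scores: np.ndarray) -> dict[str, list[float]]:
    """ROC curve operating points (for plotting or export)."""
    fpr, tpr, thresholds = roc_curve(_check_binary(true_labels, "true_labels"), scores)
    return {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "thresholds": thresholds.tolist()}


def pr_points(true_labels: np.ndarray, scores: np.ndarray) -> dict[str, list[float]]:
    """Precision-recall curve operating points."""
    precision, recall, thresholds = precision_recall_curve(
        _check_binary(true_labels, "true_labels"), scores)
    return {"precision": precision.tolist(), "recall": recall.tolist(),
            "thresholds": thresholds.tolist()}


_TSV_COLUMNS = ("tp", "tn", "fp", "fn", "sensitivity", "specificity", "accuracy",
                "precision", "aroc", "apr", "mcc", "f1")


def metrics_to_tsv_row(name: str, metrics: ClassificationMetrics,
                       header: bool = False) -> str:
    """One TSV row (optionally preceded by a header line) for a metrics set."""
    def fmt(value: float | None) -> str:
        return "" if value is None else f"{value:.4f}"

    c = metrics.counts
    fields = [name, str(c.tp), str(c.tn), str(c.fp), str(c.fn),
              fmt(metrics.sensitivity), fmt(metrics.specificity),
              fmt(metrics.accuracy), fmt(metrics.precision),
              fmt(metrics.aroc), fmt(metrics.apr), fmt(metrics.mcc), fmt(metrics.f1)]
    row = "\t".join(fields)
    if header:
        return "\t".join(("model", *_TSV_COLUMNS)) + "\n" + row
    return row


def metrics_to_json(metrics: ClassificationMetrics) -> str:
    """JSON export of a metrics set (counts inlined)."""
    payload = {
        "sensitivity": metrics.sensitivity,
        "specificity": metrics.specificity,
        "accuracy": metrics.accuracy,
        "precision": metrics.precision,
        "aroc": metrics.aroc,
        "apr": metrics.apr,
        "mcc": metrics.mcc,
        "f1": metrics.f1,
        "counts": asdict(metrics.counts),
    }
    return json.dumps(payload, sort_keys=True)
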