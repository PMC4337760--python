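"""Cross-validation, confusion matrices, per-behavior metrics, comparisons.

Three validation schemes are offered: k-fold, train-split (the k=2
special case and the default), and leave-one-out (the k=n special case).
Folds are stratified by default so that rare behaviors appear in every
validation part; when some class has fewer members than k, stratification
degrades to plain k-fold with a warning.

Per-behavior metrics follow the one-vs-rest convention: for behavior b,
accuracy_b = (TP_b + TN_b) / N, precision_b = TP_b / (TP_b + FP_b),
recall_b = TP_b / (TP_b + FN_b). A zero denominator leaves the metric
undefined (NaN), never 0; report renderers show it as an em dash and
averages exclude it. The confusion matrix and per-behavior metrics are
computed on predictions pooled over all validation folds, while the
mean/std accuracy is computed across per-fold accuracies (sample std,
divisor k-1); both views are reported.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import KFold, StratifiedKFold

from .exceptions import EvaluationError
from .io import FeatureTable
from .models import ModelSpec, predict, train

CV_KINDS = ("kfold", "train_split", "leave_one_out")

UNDEFINED = float("nan")


@dataclass(frozen=True)
class CVScheme:
    """A cross-validation layout.

    ``train_split`` is k-fold with k=2; ``leave_one_out`` is k-fold with
    k=n. Stratification preserves class proportions within +-1 sample per
    class per fold when every class has at least k members.
    """

    kind: str = "train_split"
    k: int = 2
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CV_KINDS:
            raise EvaluationError(f"kind must be one of {CV_KINDS}, got {self.kind!r}")

    def effective_k(self, n: int) -> int:
        if self.kind == "train_split":
            return 2
        if self.kind == "leave_one_out":
            return n
        return self.k


def make_folds(n: int, scheme: CVScheme,
               labels: Sequence[str] | None = None) -> list[tuple[np.ndarray, np.ndarray]]:
    """Build (train_indices, validation_indices) pairs partitioning 0..n-1.

    Every index validates exactly once and fold sizes differ by at most
    one. Reproducible under ``scheme.seed``.
    """
    k = scheme.effective_k(n)
    if k > n:
        raise EvaluationError(f"k={k} exceeds sample count n={n}")
    if k < 2:
        raise EvaluationError(f"k must be at least 2, got {k}")
    stratify = scheme.stratified and labels is not None
    if stratify:
        _, counts = np.unique(np.asarray(labels), return_counts=True)
        if counts.min() < k:
            warnings.warn(
                f"smallest class has {int(counts.min())} members < k={k}; "
                "falling back to unstratified folds", UserWarning)
            stratify = False
    if stratify:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=scheme.seed)
        split = splitter.split(np.zeros(n), np.asarray(labels))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=scheme.seed)
        split = splitter.split(np.zeros(n))
    return [(tr.copy(), va.copy()) for tr, va in split]


@dataclass
class ConfusionMatrix:
    """Square count matrix over a sorted label vocabulary; rows = true."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts must be square over the label vocabulary")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_pairs(cls, true: Sequence[str], pred: Sequence[str],
                   labels: Sequence[str] | None = None) -> "ConfusionMatrix":
        vocab = sorted(set(labels) if labels is not None else set(true) | set(pred))
        counts = _sk_confusion(list(true), list(pred), labels=vocab)
        return cls(vocab, counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.labels, name="true"),
                            columns=pd.Index(self.labels, name="predicted"))


@dataclass
class BehaviorMetrics:
    accuracy: float
    precision: float  # NaN when the behavior was never predicted
    recall: float     # NaN when the behavior never occurred


def metrics_from_confusion(cm: ConfusionMatrix
                           ) -> tuple[dict[str, BehaviorMetrics], float]:
    """Per-behavior accuracy/precision/recall and the overall accuracy."""
    n = cm.total
    if n == 0:
        raise EvaluationError("empty confusion matrix")
    counts = cm.counts
    per: dict[str, BehaviorMetrics] = {}
    for i, label in enumerate(cm.labels):
        tp = counts[i, i]
        fn = counts[i, :].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = n - tp - fn - fp
        accuracy = (tp + tn) / n
        precision = tp / (tp + fp) if tp + fp > 0 else UNDEFINED
        recall = tp / (tp + fn) if tp + fn > 0 else UNDEFINED
        per[label] = BehaviorMetrics(float(accuracy), float(precision), float(recall))
    overall = float(np.trace(counts) / n)
    return per, overall


@dataclass
class EvaluationReport:
    """Everything a model comparison needs about one cross-validated model."""

    confusion: ConfusionMatrix
    overall_accuracy: float
    per_behavior: dict[str, BehaviorMetrics]
    fold_accuracies: list[float]
    mean_accuracy: float
    std_accuracy: float

    def metrics_frame(self) -> pd.DataFrame:
        rows = {label: {"accuracy": m.accuracy, "precision": m.precision,
                        "recall": m.recall}
                for label, m in self.per_behavior.items()}
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("behavior")

    def rendered_metrics(self) -> pd.DataFrame:
        """Metrics table with undefined entries shown as an em dash."""
        frame = self.metrics_frame()
        return frame.map(lambda v: "—" if isinstance(v, float) and math.isnan(v)
                         else f"{v:.4f}")

    def macro_precision(self) -> float:
        vals = [m.precision for m in self.per_behavior.values()]
        return float(np.nanmean(vals))

    def macro_recall(self) -> float:
        vals = [m.recall for m in self.per_behavior.values()]
        return float(np.nanmean(vals))


def cross_validate(spec: ModelSpec, table: FeatureTable,
                   scheme: CVScheme) -> EvaluationReport:
    """Cross-validate one model spec on a labeled feature table.

    Each fold fits the normalizer and the classifier on the training part
    only, then predicts the held-out part; out-of-fold predictions are
    pooled into one confusion matrix.
    """
    if table.labels is None:
        raise EvaluationError("cross-validation requires a labeled table")
    labels = list(table.labels)
    folds = make_folds(table.n_rows, scheme, labels)
    vocab = sorted(set(labels))
    true_all: list[str] = []
    pred_all: list[str] = []
    fold_accuracies: list[float] = []
    for train_idx, val_idx in folds:
        train_table = table.subset(train_idx)
        if len(set(train_table.labels)) < 2:
            raise EvaluationError(
                "a training fold contains a single class; enable stratification "
                "or use a smaller k")
        bundle = train(spec, train_table)
        preds = predict(bundle, table.subset(val_idx))
        truth = [labels[i] for i in val_idx]
        true_all.extend(truth)
        pred_all.extend(preds)
        fold_accuracies.append(float(np.mean([p == t for p, t in zip(preds, truth)])))
    cm = ConfusionMatrix.from_pairs(true_all, pred_all, vocab)
    per, overall = metrics_from_confusion(cm)
    return EvaluationReport(
        confusion=cm,
        overall_accuracy=overall,
        per_behavior=per,
        fold_accuracies=fold_accuracies,
        mean_accuracy=float(np.mean(fold_accuracies)),
        std_accuracy=float(np.std(fold_accuracies, ddof=1)),
    )


# ---------------------------------------------------------------------------
# Multi-model comparison
# ---------------------------------------------------------------------------

def compare_models(reports: Mapping[str, "EvaluationReport | tuple[float, float]"]
                   ) -> pd.DataFrame:
    """Tabulate overall accuracy and fold-std per model, plus a Mean row.

    Values may be :class:`EvaluationReport` objects or raw
    ``(accuracy_pct, std_pct)`` pairs (e.g. transcribed from a published
    table). Accuracy and std are reported in percent; the final ``Mean``
    row is the arithmetic mean of each column.
    """
    if not reports:
        raise EvaluationError("no reports to compare")
    rows = []
    for family, rep in reports.items():
        if isinstance(rep, EvaluationReport):
            rows.append({
                "model": family,
                "accuracy_pct": 100.0 * rep.overall_accuracy,
                "std_pct": 100.0 * rep.std_accuracy,
                "precision_pct": 100.0 * rep.macro_precision(),
                "recall_pct": 100.0 * rep.macro_recall(),
            })
        else:
            acc, std = rep
            rows.append({"model": family, "accuracy_pct": float(acc),
                         "std_pct": float(std)})
    frame = pd.DataFrame(rows)
    mean_row = {"model": "Mean"}
    for col in frame.columns:
        if col != "model":
            mean_row[col] = float(frame[col].mean())
    return pd.concat([frame, pd.DataFrame([mean_row])], ignore_index=True)


def precision_recall_points(reports: Mapping[str, EvaluationReport]) -> pd.DataFrame:
    """Macro precision/recall per model, for a precision-recall scatter."""
    rows = [{"model": family,
             "precision_pct": 100.0 * rep.macro_precision(),
             "recall_pct": 100.0 * rep.macro_recall()}
            for family, rep in reports.items()]
    return pd.DataFrame(rows)


def plot_accuracy_comparison(table: pd.DataFrame, path: str) -> None:
    """Bar chart of per-model overall accuracy (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    body = table[table["model"] != "Mean"]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(body["model"], body["accuracy_pct"],
           yerr=body.get("std_pct"), capsize=3)
    ax.set_ylabel("overall accuracy (%)")
    ax.set_ylim(0, 100)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_precision_recall(points: pd.DataFrame, path: str) -> None:
    """Precision-recall scatter across models (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(points["recall_pct"], points["precision_pct"])
    for _, rec in points.iterrows():
        ax.annotate(rec["model"], (rec["recall_pct"], rec["precision_pct"]),
                    fontsize=8)
    ax.set_xlabel("recall (%)")
    ax.set_ylabel("precision (%)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
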