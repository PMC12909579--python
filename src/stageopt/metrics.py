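"""Classification metrics for the four-stage dementia grading task.

Implements accuracy, per-class precision/recall/F1 (one-vs-rest), the binary
Matthews correlation coefficient and its K-class generalization (Gorodkin's
R_K statistic), macro and support-weighted aggregation, and reconstruction of
confusion-matrix marginals from a published per-class table.  The multiclass
MCC is the optimization objective of the whole framework, so this module is
the single source of truth for fitness values.

Conventions: multiclass accuracy is trace/total; any rate with a zero
denominator (empty class, zero MCC root) is reported as 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "ClassificationReport",
    "confusion_matrix",
    "f1_score",
    "per_class_metrics",
    "accuracy_error",
    "mcc_binary",
    "mcc_multiclass",
    "mcc_from_marginals",
    "aggregate",
    "reconstruct_marginals",
    "classification_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K count matrix: rows index the true class, columns the prediction."""

    counts: np.ndarray
    class_labels: tuple

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.class_labels) != c.shape[0]:
            raise ValueError("label count must match matrix size")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        """Per-class number of true samples (row sums)."""
        return self.counts.sum(axis=1)


def confusion_matrix(
    y_true: Sequence, y_pred: Sequence, labels: Sequence
) -> ConfusionMatrix:
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label {t if t not in index else p!r} not in labels")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(labels))


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    return _safe_div(2 * precision * recall, precision + recall)


def per_class_metrics(cm: ConfusionMatrix) -> dict:
    """One-vs-rest precision, recall and F1 per class, with supports.

    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R); any zero
    denominator yields 0.
    """
    counts = cm.counts
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp  # column total minus diagonal
    fn = counts.sum(axis=1) - tp  # row total minus diagonal
    precision = np.array([_safe_div(t, t + f) for t, f in zip(tp, fp)])
    recall = np.array([_safe_div(t, t + f) for t, f in zip(tp, fn)])
    f1 = np.array(
        [_safe_div(2 * p * r, p + r) for p, r in zip(precision, recall)]
    )
    return {
        "labels": list(cm.class_labels),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "support": cm.supports.copy(),
    }


def accuracy_error(cm: ConfusionMatrix) -> tuple[float, float]:
    """(accuracy, error rate): trace over total, and its complement."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = float(np.trace(cm.counts)) / total
    return acc, 1.0 - acc


def mcc_binary(tp: int, tn: int, fp: int, fn: int) -> float:
    for name, v in (("tp", tp), ("tn", tn), ("fp", fp), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    num = tp * tn - fp * fn
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        return 0.0
    return num / math.sqrt(den)


def mcc_from_marginals(
    diagonal: Sequence[float],
    row_totals: Sequence[float],
    col_totals: Sequence[float],
) -> float:
    """Gorodkin's R_K from confusion-matrix marginals alone.

    With c = sum of the diagonal, s = total sample count, t_k the row (true)
    totals and p_k the column (predicted) totals:

        R_K = (c*s - sum_k p_k t_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2))

    A zero denominator (all mass in one row or one column) yields 0.
    """
    t = np.asarray(row_totals, dtype=float)
    p = np.asarray(col_totals, dtype=float)
    c = float(np.sum(diagonal))
    s = float(t.sum())
    num = c * s - float(p @ t)
    den = (s * s - float(p @ p)) * (s * s - float(t @ t))
    if den <= 0:
        return 0.0
    return num / math.sqrt(den)


def mcc_multiclass(cm: ConfusionMatrix) -> float:
    """K-class Matthews correlation coefficient (R_K statistic)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return mcc_from_marginals(
        np.diag(cm.counts), cm.counts.sum(axis=1), cm.counts.sum(axis=0)
    )


def aggregate(
    values: Sequence[float], supports: Sequence[float]
) -> tuple[float, float]:
    """(macro, weighted) averages of a per-class metric vector."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(supports, dtype=float)
    if (w <= 0).any():
        raise ValueError("supports must be positive")
    return float(v.mean()), float((v * w).sum() / w.sum())


def reconstruct_marginals(
    precision: Sequence[float],
    recall: Sequence[float],
    supports: Sequence[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Recover diagonal counts and predicted-class totals from a printed table.

    diagonal_k = round(recall_k * support_k); column_k = round(diagonal_k /
    precision_k).  The reconstruction is rejected if predicted totals fail to
    conserve the sample count by more than K (one rounding unit per class).
    """
    p = np.asarray(precision, dtype=float)
    r = np.asarray(recall, dtype=float)
    s = np.asarray(supports, dtype=float)
    if ((r > 0) & (p <= 0)).any():
        raise ValueError("precision must be positive wherever recall is positive")
    diagonal = np.rint(r * s).astype(np.int64)
    columns = np.array(
        [int(round(d / pk)) if d > 0 else 0 for d, pk in zip(diagonal, p)],
        dtype=np.int64,
    )
    k = len(p)
    if abs(int(columns.sum()) - int(s.sum())) > k:
        raise ValueError(
            "reconstructed predicted totals violate sample conservation: "
            f"{int(columns.sum())} vs {int(s.sum())}"
        )
    return diagonal, columns


@dataclass
class ClassificationReport:
    """All headline metrics of one model on one evaluation split."""

    labels: list
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    error_rate: float
    mcc: float
    macro_avg: dict = field(default_factory=dict)
    weighted_avg: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        per_class = {
            str(lab): {
                "precision": float(self.precision[i]),
                "recall": float(self.recall[i]),
                "f1": float(self.f1[i]),
                "support": int(self.support[i]),
            }
            for i, lab in enumerate(self.labels)
        }
        return {
            "per_class": per_class,
            "accuracy": self.accuracy,
            "error_rate": self.error_rate,
            "mcc": self.mcc,
            "macro_avg": self.macro_avg,
            "weighted_avg": self.weighted_avg,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_csv(self, path) -> None:
        """Published-table layout: one row per metric, one column per class,
        plus accuracy / macro / weighted columns and a supports row."""
        lines = [
            "metric,"
            + ",".join(str(lab) for lab in self.labels)
            + ",accuracy,macro_avg,weighted_avg"
        ]
        for key, vec in (
            ("precision", self.precision),
            ("recall", self.recall),
            ("f1", self.f1),
        ):
            cells = [f"{v:.6f}" for v in vec]
            lines.append(
                f"{key}," + ",".join(cells)
                + f",{self.accuracy:.6f},{self.macro_avg[key]:.6f}"
                + f",{self.weighted_avg[key]:.6f}"
            )
        lines.append(
            "support," + ",".join(str(int(s)) for s in self.support) + ",,,"
        )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def report_from_confusion(cm: ConfusionMatrix) -> ClassificationReport:
    per = per_class_metrics(cm)
    acc, err = accuracy_error(cm)
    supports = per["support"]
    macro = {}
    weighted = {}
    for key in ("precision", "recall", "f1"):
        m, w = aggregate(per[key], np.maximum(supports, 1))
        # classes with zero support contribute 0 to both averages
        macro[key], weighted[key] = m, (
            float((per[key] * supports).sum() / supports.sum())
            if supports.sum() > 0
            else 0.0
        )
    return ClassificationReport(
        labels=per["labels"],
        precision=per["precision"],
        recall=per["recall"],
        f1=per["f1"],
        support=supports,
        accuracy=acc,
        error_rate=err,
        mcc=mcc_multiclass(cm),
        macro_avg=macro,
        weighted_avg=weighted,
    )


def classification_report(
    y_true: Sequence, y_pred: Sequence, labels: Sequence
) -> ClassificationReport:
    """Full report (per-class metrics, accuracy, MCC, macro/weighted means)."""
    return report_from_confusion(confusion_matrix(y_true, y_pred, labels))
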