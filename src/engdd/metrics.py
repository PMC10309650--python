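"""Evaluation metrics: precision, recall, accuracy, F1, AUC, AUPR.

AUC is computed as the tie-aware Mann-Whitney rank statistic (exact,
O(n log n)), not by trapezoid integration over sampled thresholds.
AUPR is the average-precision form of the precision-recall step curve.
Zero-denominator conventions: precision := 0 when no pair is predicted
positive; F1 := 0 when precision + recall = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

METRIC_NAMES = ("precision", "recall", "accuracy", "f1", "auc", "aupr")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_labels(cls, y_true: np.ndarray,
                    y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(tp=int(np.sum((y_true == 1) & (y_pred == 1))),
                   fp=int(np.sum((y_true == 0) & (y_pred == 1))),
                   fn=int(np.sum((y_true == 1) & (y_pred == 0))),
                   tn=int(np.sum((y_true == 0) & (y_pred == 0))))


def confusion_metrics(counts: ConfusionCounts
                      ) -> tuple[float, float, float, float]:
    """(precision, recall, accuracy, F1) from a confusion table."""
    if counts.n == 0:
        raise ValueError("empty confusion table")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    accuracy = (tp + tn) / counts.n
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, accuracy, f1


def roc_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for AUC")
    ranks = rankdata(scores)  # midranks handle ties
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def pr_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Average precision: sum over recall increments of precision."""
    y = np.asarray(y, dtype=int)
    if y.sum() in (0, len(y)):
        raise ValueError("both classes required for AUPR")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def all_metrics(y_true: np.ndarray, scores: np.ndarray,
                threshold: float = 0.5) -> dict[str, float]:
    """All six metrics at the strict > threshold decision rule."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    y_pred = (scores > threshold).astype(int)
    precision, recall, accuracy, f1 = confusion_metrics(
        ConfusionCounts.from_labels(y_true, y_pred))
    return {
        "precision": precision, "recall": recall, "accuracy": accuracy,
        "f1": f1, "auc": roc_auc(scores, y_true),
        "aupr": pr_auc(scores, y_true),
    }


@dataclass
class MetricsReport:
    """Per-repetition metric values plus their mean/std summary."""

    per_repetition: pd.DataFrame  # one row per repetition, METRIC_NAMES cols

    @property
    def n_repetitions(self) -> int:
        return len(self.per_repetition)

    @property
    def mean(self) -> pd.Series:
        return self.per_repetition[list(METRIC_NAMES)].mean()

    @property
    def std(self) -> pd.Series:
        return self.per_repetition[list(METRIC_NAMES)].std(ddof=1)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "std": self.std})

    def to_tsv(self, path) -> None:
        df = self.per_repetition.copy()
        df.insert(0, "repetition", range(len(df)))
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "MetricsReport":
        df = pd.read_csv(path, sep="\t")
        return cls(df.drop(columns=["repetition"]))
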