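"""Multi-class evaluation: confusion matrix, one-vs-rest metrics, correlations.

Per-class metrics follow the one-vs-rest convention: for each class the
3x3 confusion matrix collapses to TP/TN/FP/FN and yields sensitivity
(recall), specificity, precision, accuracy (TP+TN)/N and the F1 score
(harmonic mean of precision and sensitivity).  Cells whose denominator is
zero are reported as NaN rather than zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

__all__ = [
    "STRESS_LABELS",
    "ConfusionMatrix",
    "CorrelationResult",
    "confusion",
    "per_class_metrics",
    "f1_score",
    "correlate",
]

STRESS_LABELS: tuple[str, ...] = ("Calm", "Normal", "Stressed")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts[i, j] = records with true label i predicted as label j."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if counts.shape != (k, k):
            raise InvalidInputError(
                f"counts shape {counts.shape} does not match {k} labels"
            )
        if np.any(counts < 0):
            raise InvalidInputError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class CorrelationResult:
    pearson: float
    spearman: float
    n: int


def confusion(
    true: Sequence[str],
    predicted: Sequence[str],
    labels: Sequence[str] = STRESS_LABELS,
) -> ConfusionMatrix:
    """Tally a multi-class confusion matrix (rows true, columns predicted)."""
    if len(true) != len(predicted):
        raise InvalidInputError(
            f"length mismatch: {len(true)} true vs {len(predicted)} predicted"
        )
    if len(true) == 0:
        raise InvalidInputError("cannot build a confusion matrix from zero records")
    index = {label: i for i, label in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(true, predicted):
        if t not in index or p not in index:
            raise InvalidInputError(
                f"unknown label in pair ({t!r}, {p!r}); expected one of {list(labels)}"
            )
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(labels=tuple(labels), counts=counts)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def f1_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity; NaN if undefined."""
    if math.isnan(precision) or math.isnan(sensitivity):
        return float("nan")
    return _safe_div(2.0 * precision * sensitivity, precision + sensitivity)


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """One-vs-rest sensitivity/specificity/precision/accuracy/F1 per class.

    Returns a DataFrame with metrics as rows and class labels as columns;
    undefined ratios are NaN.
    """
    if cm.total == 0:
        raise InvalidInputError("empty confusion matrix")
    n = cm.total
    out = {}
    for i, label in enumerate(cm.labels):
        tp = float(cm.counts[i, i])
        fn = float(cm.counts[i, :].sum() - tp)
        fp = float(cm.counts[:, i].sum() - tp)
        tn = float(n - tp - fn - fp)
        sens = _safe_div(tp, tp + fn)
        prec = _safe_div(tp, tp + fp)
        out[label] = {
            "sensitivity": sens,
            "specificity": _safe_div(tn, tn + fp),
            "precision": prec,
            "accuracy": (tp + tn) / n,
            "f1": f1_score(prec, sens),
        }
    return pd.DataFrame(out)


def correlate(a: Sequence[float], b: Sequence[float]) -> CorrelationResult:
    """Pearson and Spearman correlation of two paired series.

    A constant series makes Pearson undefined (NaN); Spearman uses midranks
    and is likewise NaN when a rank vector is constant.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("series must be one-dimensional and equally long")
    if len(x) < 3:
        raise InvalidInputError("need at least 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidInputError("series must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        pearson = float("nan")
        spearman = float("nan")
    else:
        pearson = float(stats.pearsonr(x, y).statistic)
        spearman = float(stats.spearmanr(x, y).statistic)
    return CorrelationResult(pearson=pearson, spearman=spearman, n=len(x))
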