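"""Model evaluation: micro-averaged classification metrics, regression
metrics, pooled one-vs-rest ROC curves, and scatter-plot data export.

Micro averaging pools every (instance, class) one-vs-rest decision before
computing precision/recall/F1. For single-label multiclass predictions this
makes accuracy, micro-precision, micro-recall and micro-F1 identical — which
is why a well-behaved multiclass report shows one repeated number across
those four rows. Macro and weighted averaging remain available behind the
``average`` flag.

R^2 is computed as ``1 - MSE / Var(y_true)`` with the population variance;
a zero-variance truth vector leaves R^2 undefined and is reported as such
rather than silently coerced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    auc as _auc,
    precision_recall_fscore_support,
    roc_curve,
)
from sklearn.preprocessing import label_binarize

from .errors import ConfigurationError


@dataclass(frozen=True)
class ConfusionTally:
    """Binary confusion counts with the textbook metric formulas attached."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ConfigurationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r)


@dataclass
class MetricsReport:
    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    mse: float | None = None
    mae: float | None = None
    r2: float | None = None
    r2_defined: bool = True
    auc_micro: float | None = None
    roc_points: np.ndarray | None = None
    averaging: str = "micro"

    def as_dict(self) -> dict:
        out = {}
        for k in ("accuracy", "precision", "recall", "f1", "mse", "mae", "r2", "auc_micro"):
            v = getattr(self, k)
            if v is not None:
                out[k] = float(v)
        if not self.r2_defined:
            out["r2"] = None
        out["averaging"] = self.averaging
        return out


def _check_pair(y_true, y_pred, min_n: int = 1):
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ConfigurationError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")
    if len(y_true) < min_n:
        raise ConfigurationError(f"need at least {min_n} observations, got {len(y_true)}")
    return y_true, y_pred


def classification_metrics(y_true, y_pred, average: str = "micro") -> MetricsReport:
    """Multiclass accuracy/precision/recall/F1 with micro averaging by default."""
    y_true, y_pred = _check_pair(y_true, y_pred, min_n=1)
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average=average, zero_division=0
    )
    return MetricsReport(
        accuracy=accuracy_score(y_true, y_pred),
        precision=precision,
        recall=recall,
        f1=f1,
        averaging=average,
    )


def regression_metrics(y_true, y_pred) -> MetricsReport:
    """MSE, MAE, and R^2 = 1 - MSE / population variance of the truth."""
    y_true, y_pred = _check_pair(y_true, y_pred, min_n=2)
    y_true = y_true.astype(float)
    y_pred = y_pred.astype(float)
    err = y_pred - y_true
    mse = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    var = float(np.var(y_true))  # population variance
    if var == 0:
        return MetricsReport(mse=mse, mae=mae, r2=None, r2_defined=False, averaging="n/a")
    return MetricsReport(mse=mse, mae=mae, r2=1 - mse / var, averaging="n/a")


def roc_micro(
    y_true, scores, classes: Sequence[int] | None = None
) -> tuple[np.ndarray, float]:
    """Micro-average ROC: binarize one-vs-rest, pool all (label, score) pairs,
    sweep thresholds, integrate by trapezoid.

    ``scores`` is an (n, n_classes) matrix whose columns follow ``classes``
    (default: sorted observed classes). Returns ``(points, auc)`` where
    points is an array of (fpr, tpr) rows from (0,0) to (1,1).
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if classes is None:
        classes = np.unique(y_true)
    classes = np.asarray(classes)
    observed = np.unique(y_true)
    missing = set(observed.tolist()) - set(classes.tolist())
    if missing:
        raise ConfigurationError(f"classes {sorted(missing)} absent from score matrix")
    if scores.ndim != 2 or scores.shape != (len(y_true), len(classes)):
        raise ConfigurationError(
            f"score matrix must be ({len(y_true)}, {len(classes)}), got {scores.shape}"
        )
    y_bin = label_binarize(y_true, classes=classes)
    if y_bin.shape[1] == 1:  # sklearn collapses the binary case to one column
        y_bin = np.hstack([1 - y_bin, y_bin])
    fpr, tpr, _ = roc_curve(y_bin.ravel(), scores.ravel())
    points = np.column_stack([fpr, tpr])
    return points, float(_auc(fpr, tpr))


def scatter_export(y_true, y_pred) -> pd.DataFrame:
    """Aggregate (true, predicted) pairs with multiplicities for re-plotting."""
    if len(np.asarray(y_true)) == 0:
        return pd.DataFrame(columns=["true", "predicted", "count"])
    y_true, y_pred = _check_pair(y_true, y_pred)
    df = pd.DataFrame({"true": y_true, "predicted": y_pred})
    out = df.value_counts().reset_index(name="count")
    return out.sort_values(["true", "predicted"]).reset_index(drop=True)
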