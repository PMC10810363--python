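"""Performance metrics for classification and regression.

Classification metrics are defined on the 2x2 table of confusion (confusion
matrix) for a declared positive class; multiclass problems are handled
one-vs-rest per class and combined by macro (or count-weighted) averaging.
Each metric carries an optimisation direction so downstream model selection
knows whether smaller or larger is better.

Undefined scores (zero denominators, e.g. precision with no positive
predictions) are signalled as NaN -- the package-wide missing-score marker --
rather than silently coerced to 0; aggregation stages exclude them and record
how many were dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricSpec",
    "get_metric",
    "confusion_matrix",
    "classification_score",
    "regression_score",
    "multiclass_average",
    "score_predictions",
    "CLASSIFICATION_METRICS",
    "REGRESSION_METRICS",
]

#: metric name -> optimisation direction
_DIRECTIONS = {
    "err": "minimize",
    "acc": "maximize",
    "precision": "maximize",
    "sensitivity": "maximize",
    "f1": "maximize",
    "mse": "minimize",
    "rmse": "minimize",
    "mae": "minimize",
    "mape": "minimize",
    "r2": "maximize",
}

CLASSIFICATION_METRICS = ("err", "acc", "precision", "sensitivity", "f1")
REGRESSION_METRICS = ("mse", "rmse", "mae", "mape", "r2")


@dataclass(frozen=True)
class MetricSpec:
    """A named performance measure plus its optimisation direction.

    ``epsilon`` guards the division by zero in MAPE (an arbitrary small
    positive number; only consulted for ``mape``).
    """

    name: str
    direction: str
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if self.name not in _DIRECTIONS:
            raise ValueError(f"unknown metric {self.name!r}")
        if self.direction != _DIRECTIONS[self.name]:
            raise ValueError(
                f"metric {self.name!r} must have direction {_DIRECTIONS[self.name]!r}"
            )
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def minimize(self) -> bool:
        return self.direction == "minimize"

    @property
    def is_classification(self) -> bool:
        return self.name in CLASSIFICATION_METRICS


def get_metric(name: str, epsilon: float = 1e-8) -> MetricSpec:
    """Look up a metric by its lowercase name (as accepted in configs)."""
    name = name.lower()
    if name not in _DIRECTIONS:
        raise ValueError(
            f"unknown metric {name!r}; choose from {sorted(_DIRECTIONS)}"
        )
    return MetricSpec(name=name, direction=_DIRECTIONS[name], epsilon=epsilon)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 table of confusion for one positive class.

    The four cells partition the scored observations; the derived margins are
    P = TP+FN (actual positives), N = FP+TN (actual negatives),
    PP = TP+FP (predicted positives), PN = FN+TN (predicted negatives).
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.tn, self.fn):
            if v < 0:
                raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @property
    def pp(self) -> int:
        return self.tp + self.fp

    @property
    def pn(self) -> int:
        return self.fn + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_matrix(y_true, y_pred, positive) -> ConfusionMatrix:
    """Count TP/FP/TN/FN of ``y_pred`` against ``y_true`` for one positive label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("empty input")
    labels = set(np.unique(y_true)) | set(np.unique(y_pred))
    if positive not in labels:
        raise ValueError(f"positive label {positive!r} not in label alphabet")
    t = y_true == positive
    h = y_pred == positive
    return ConfusionMatrix(
        tp=int(np.sum(t & h)),
        fp=int(np.sum(~t & h)),
        tn=int(np.sum(~t & ~h)),
        fn=int(np.sum(t & ~h)),
    )


def classification_score(cm: ConfusionMatrix, metric: MetricSpec | str) -> float:
    """Score one confusion matrix.

    err = (FP+FN)/total, acc = (TP+TN)/total = 1-err, precision = TP/PP,
    sensitivity = TP/P, F1 = harmonic mean of precision and sensitivity.
    Returns NaN where the denominator is zero.
    """
    if isinstance(metric, str):
        metric = get_metric(metric)
    if cm.total == 0:
        raise ValueError("confusion matrix with no observations")
    name = metric.name
    if name == "acc":
        return (cm.tp + cm.tn) / cm.total
    if name == "err":
        return (cm.fp + cm.fn) / cm.total
    if name == "precision":
        return cm.tp / cm.pp if cm.pp > 0 else math.nan
    if name == "sensitivity":
        return cm.tp / cm.p if cm.p > 0 else math.nan
    if name == "f1":
        # TP / (TP + (FP+FN)/2); undefined when TP, FP and FN are all zero
        denom = cm.tp + 0.5 * (cm.fp + cm.fn)
        return cm.tp / denom if denom > 0 else math.nan
    raise ValueError(f"{name!r} is not a classification metric")


def regression_score(y_true, y_pred, metric: MetricSpec | str) -> float:
    """Score real-valued predictions: mse, rmse, mae, mape or r2.

    MAPE divides each absolute error by max(|y_i|, epsilon); R2 is
    1 - SS_res/SS_tot and is NaN when y_true is constant (zero variance).
    """
    if isinstance(metric, str):
        metric = get_metric(metric)
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("empty input")
    name = metric.name
    resid = y_true - y_pred
    if name == "mse":
        return float(np.mean(resid**2))
    if name == "rmse":
        return float(np.sqrt(np.mean(resid**2)))
    if name == "mae":
        return float(np.mean(np.abs(resid)))
    if name == "mape":
        denom = np.maximum(np.abs(y_true), metric.epsilon)
        return float(np.mean(np.abs(resid) / denom))
    if name == "r2":
        ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
        if ss_tot == 0:
            return math.nan
        return 1.0 - float(np.sum(resid**2)) / ss_tot
    raise ValueError(f"{name!r} is not a regression metric")


def multiclass_average(per_class_scores, weights=None) -> float:
    """Combine per-class scores: macro mean, or weighted by class counts.

    NaN entries (undefined per-class scores) are excluded together with their
    weights; returns NaN if every class score is undefined.
    """
    s = np.asarray(per_class_scores, dtype=float)
    if s.size == 0:
        raise ValueError("no class scores to average")
    if weights is None:
        w = np.ones_like(s)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != s.shape:
            raise ValueError("weights must match scores in length")
    ok = ~np.isnan(s)
    if not ok.any():
        return math.nan
    return float(np.sum(w[ok] * s[ok]) / np.sum(w[ok]))


def score_predictions(
    y_true,
    y_pred,
    metric: MetricSpec | str,
    task: str,
    positive=None,
) -> float:
    """Uniform scoring entry point used by the evaluation engine.

    Regression metrics delegate to :func:`regression_score`. Binary
    classification with a declared positive class scores that class's
    confusion matrix; without one (or with >2 classes) each class is scored
    one-vs-rest and the scores macro-averaged.
    """
    if isinstance(metric, str):
        metric = get_metric(metric)
    if task == "regression":
        return regression_score(y_true, y_pred, metric)
    if task != "classification":
        raise ValueError(f"unknown task {task!r}")
    if not metric.is_classification:
        raise ValueError(f"metric {metric.name!r} is not defined for classification")
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = np.unique(y_true)
    if positive is not None and (labels.size <= 2):
        cm = confusion_matrix(y_true, y_pred, positive)
        return classification_score(cm, metric)
    if metric.name in ("acc", "err"):
        # plain (micro) accuracy; identical to the per-class one-vs-rest value
        # for binary problems and the conventional reading for multiclass
        acc = float(np.mean(y_true == y_pred))
        return acc if metric.name == "acc" else 1.0 - acc
    per_class = [
        classification_score(confusion_matrix(y_true, y_pred, lab), metric)
        for lab in labels
    ]
    return multiclass_average(per_class)
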