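"""Performance-weighted aggregation of per-model feature importance.

Each model j fitted during the evaluation contributes, for every feature i,

    importance_ij = presence_ij * sign_ij * stability_ij

(presence 0/1, coefficient sign -1/0/+1 where applicable else 0, tuning
stability in [0, 1]), and carries a weight derived from its performance:
performance^2 for maximized metrics, 1 / (performance + epsilon)^2 for
minimized ones (epsilon guards the division by zero). The global feature
importance score is the weighted mean over ALL models of the evaluation --
every size, every repeat:

    FIS_i = sum_j weight_j * importance_ij / sum_j weight_j

Tree-ensemble and kNN models have sign 0 everywhere, so their FIS is 0 by
construction; the support and stability columns remain informative there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import MethodEvaluation, ModelRecord
from .metrics import MetricSpec, get_metric

__all__ = ["ImportanceTable", "model_weight", "model_importance", "aggregate_importance"]


@dataclass
class ImportanceTable:
    """Per-feature FIS plus support counts and the weights that produced it."""

    feature_names: list[str]
    fis: np.ndarray
    support: np.ndarray  # models in which the feature was present
    mean_stability: np.ndarray  # over the models where present (0 if never)
    weights: np.ndarray  # one per contributing model
    epsilon: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.feature_names,
            "fis": self.fis,
            "support": self.support,
            "mean_stability": self.mean_stability,
        })

    def save(self, path) -> None:
        self.frame().to_csv(path, index=False)


def model_weight(performance: float, direction: str, epsilon: float = 1e-8) -> float:
    """Weight of one model from its performance: square the metric.

    Maximized metrics reward large values (performance^2); minimized metrics
    reward small errors (1 / (performance + epsilon)^2). Always positive.
    """
    if not math.isfinite(performance):
        raise ValueError("performance must be finite")
    if direction == "maximize":
        return float(performance) ** 2
    if direction == "minimize":
        if performance < 0:
            raise ValueError("minimized metrics are non-negative")
        return 1.0 / (performance + epsilon) ** 2
    raise ValueError(f"unknown direction {direction!r}")


def model_importance(record: ModelRecord) -> np.ndarray:
    """importance_ij = presence * sign * stability, elementwise per feature."""
    return (
        record.feature_presence.astype(float)
        * record.feature_sign.astype(float)
        * record.feature_stability
    )


def aggregate_importance(
    ev: MethodEvaluation,
    metric: MetricSpec | str | None = None,
    epsilon: float = 1e-8,
    data_slice: str = "test",
) -> ImportanceTable:
    """Weighted-mean FIS over every model of the evaluation.

    Weights come from each model's ``data_slice`` score of ``metric`` (default
    the evaluation's primary metric on the test slice). Models that failed, or
    whose weighting score is undefined, contribute neither weight nor
    importance. Features never present in any model have FIS exactly 0.
    """
    m = get_metric(metric) if isinstance(metric, str) else (metric or get_metric(ev.metrics[0]))
    p = len(ev.feature_names)
    num = np.zeros(p)
    support = np.zeros(p, dtype=np.int64)
    stab_sum = np.zeros(p)
    weights = []
    for r in ev.records:
        if r.failed:
            continue
        perf = r.scores.get(data_slice, {}).get(m.name, math.nan)
        if not math.isfinite(perf):
            continue
        w = model_weight(perf, m.direction, epsilon)
        weights.append(w)
        num += w * model_importance(r)
        support += r.feature_presence.astype(np.int64)
        stab_sum += r.feature_presence * r.feature_stability
    if not weights:
        raise ValueError("no model contributed a defined weighting score")
    total = float(np.sum(weights))
    assert total > 0
    with np.errstate(invalid="ignore"):
        mean_stab = np.where(support > 0, stab_sum / np.maximum(support, 1), 0.0)
    return ImportanceTable(
        feature_names=list(ev.feature_names),
        fis=num / total,
        support=support,
        mean_stability=mean_stab,
        weights=np.asarray(weights),
        epsilon=epsilon,
    )
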