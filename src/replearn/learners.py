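"""Uniform adapter over established learner implementations.

Five families are exposed behind one fit/predict surface: penalized GLMs
(lasso / ridge / elastic-net), random forests, linear-kernel SVMs, gradient
boosting and k-nearest neighbours, each delegating to scikit-learn. The
adapter contributes what the evaluation engine needs and the underlying
libraries do not standardise:

* a declared hyperparameter grid with a **complexity order** (which
  configuration counts as "simpler", required by the one-standard-error rule);
* per-feature **presence** (0/1) and **sign** (-1/0/+1) after fitting -- for
  coefficient models presence means a nonzero coefficient; for tree ensembles
  it means nonzero split importance with sign fixed at 0; for kNN every
  feature is present (all enter the distance) with sign 0;
* feature-space alignment **by name**: prediction reorders columns to the
  training layout and a missing or extra dimension is an error, never a
  silent positional match.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.svm import LinearSVC, LinearSVR

__all__ = ["LearnerSpec", "TrainedModel", "fit", "predict", "decision_value", "default_grid"]

FAMILIES = ("glm_penalized", "random_forest", "svm_linear", "gbm", "knn")


def default_grid(family: str, task: str, preset: Optional[str] = None) -> dict:
    """A small, sensible hyperparameter grid per family.

    ``preset`` narrows the penalized GLM to ``lasso`` (l1_ratio 1), ``ridge``
    (l1_ratio 0) or ``elasticnet`` (l1_ratio 0.5).
    """
    if family == "glm_penalized":
        l1 = {"lasso": [1.0], "ridge": [0.0], "elasticnet": [0.5]}.get(
            preset, [0.0, 0.5, 1.0]
        )
        return {"alpha": [0.001, 0.01, 0.1, 1.0], "l1_ratio": l1}
    if family == "random_forest":
        return {"n_estimators": [100, 300], "max_depth": [None]}
    if family == "svm_linear":
        return {"C": [0.01, 0.1, 1.0, 10.0]}
    if family == "gbm":
        return {"n_estimators": [50, 100], "max_depth": [2, 3]}
    if family == "knn":
        return {"n_neighbors": [3, 5, 11, 21]}
    raise ValueError(f"unknown learner family {family!r}")


@dataclass(frozen=True)
class LearnerSpec:
    """A learner family, its task, and the hyperparameter grid to search."""

    family: str
    task: str  # classification | regression
    grid: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}")
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if not self.grid:
            object.__setattr__(self, "grid", default_grid(self.family, self.task))
        if any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("grid value lists must be non-empty")

    def configurations(self) -> list[dict]:
        """Expand the grid into configurations, deterministic order."""
        keys = list(self.grid)
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(self.grid[k] for k in keys))
        ]

    def complexity_key(self, config: dict) -> tuple:
        """Total order over configurations; LARGER key = SIMPLER model.

        GLM: larger penalty (then sparser l1 mix) is simpler. kNN: larger k is
        simpler (smoother). Forest/boosting: fewer, shallower trees are
        simpler. Linear SVM: stronger regularisation (smaller C) is simpler.
        """
        f = self.family
        if f == "glm_penalized":
            return (config["alpha"], config.get("l1_ratio", 0.0))
        if f == "knn":
            return (config["n_neighbors"],)
        if f == "svm_linear":
            return (-config["C"],)
        if f == "random_forest":
            depth = config.get("max_depth") or float("inf")
            return (-config["n_estimators"], -depth)
        if f == "gbm":
            depth = config.get("max_depth") or float("inf")
            return (-config["n_estimators"], -depth)
        raise ValueError(f"unknown learner family {f!r}")


@dataclass
class TrainedModel:
    """One fitted model plus the feature bookkeeping importance needs."""

    spec: LearnerSpec
    configuration: dict
    estimator: object
    feature_names: list[str]
    feature_presence: np.ndarray  # 0/1 per feature
    feature_sign: np.ndarray  # -1/0/+1 per feature

    def predict(self, X) -> np.ndarray:
        return predict(self, X)

    def decision_value(self, X) -> Optional[np.ndarray]:
        return decision_value(self, X)


def _make_estimator(spec: LearnerSpec, config: dict, seed: Optional[int]):
    f, task = spec.family, spec.task
    cls = task == "classification"
    if f == "glm_penalized":
        alpha = config["alpha"]
        l1_ratio = config.get("l1_ratio", 1.0)
        if cls:
            if alpha <= 0:
                return LogisticRegression(penalty=None, max_iter=2000)
            return LogisticRegression(
                penalty="elasticnet",
                solver="saga",
                C=1.0 / alpha,
                l1_ratio=l1_ratio,
                max_iter=5000,
                tol=1e-4,
            )
        if alpha <= 0:
            from sklearn.linear_model import LinearRegression

            return LinearRegression()
        return ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=10000)
    if f == "random_forest":
        klass = RandomForestClassifier if cls else RandomForestRegressor
        return klass(
            n_estimators=config.get("n_estimators", 100),
            max_depth=config.get("max_depth"),
            random_state=seed,
        )
    if f == "svm_linear":
        if cls:
            return LinearSVC(C=config["C"], max_iter=20000, random_state=seed)
        return LinearSVR(C=config["C"], max_iter=20000, random_state=seed)
    if f == "gbm":
        klass = GradientBoostingClassifier if cls else GradientBoostingRegressor
        return klass(
            n_estimators=config.get("n_estimators", 100),
            max_depth=config.get("max_depth", 3),
            learning_rate=config.get("learning_rate", 0.1),
            random_state=seed,
        )
    if f == "knn":
        klass = KNeighborsClassifier if cls else KNeighborsRegressor
        return klass(n_neighbors=config["n_neighbors"])
    raise ValueError(f"unknown learner family {f!r}")


def _presence_sign(spec: LearnerSpec, est, p: int) -> tuple[np.ndarray, np.ndarray]:
    if spec.family in ("glm_penalized", "svm_linear"):
        coef = np.asarray(getattr(est, "coef_", np.zeros(p)))
        if coef.ndim == 1:
            presence = (coef != 0).astype(np.int8)
            sign = np.sign(coef).astype(np.int8)
        elif coef.shape[0] == 1:
            presence = (coef[0] != 0).astype(np.int8)
            sign = np.sign(coef[0]).astype(np.int8)
        else:  # multiclass: a feature is present if any class uses it; sign n/a
            presence = (coef != 0).any(axis=0).astype(np.int8)
            sign = np.zeros(p, dtype=np.int8)
        return presence, sign
    if spec.family in ("random_forest", "gbm"):
        imp = np.asarray(est.feature_importances_)
        return (imp > 0).astype(np.int8), np.zeros(p, dtype=np.int8)
    # knn: all features enter the distance computation
    return np.ones(p, dtype=np.int8), np.zeros(p, dtype=np.int8)


def _to_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


def fit(spec: LearnerSpec, configuration: dict, X_train, y_train, seed: Optional[int] = None) -> TrainedModel:
    """Fit one configuration on a complete training matrix.

    Deterministic given ``seed`` (passed to stochastic estimators). Missing
    values and single-class classification responses are errors.
    """
    X = _to_frame(X_train)
    if X.isna().to_numpy().any():
        raise ValueError("training matrix contains missing values")
    y = np.asarray(y_train)
    if len(y) != len(X):
        raise ValueError("X and y length mismatch")
    if spec.task == "classification" and len(np.unique(y)) < 2:
        raise ValueError("training response has a single class")
    est = _make_estimator(spec, configuration, seed)
    est.fit(X.to_numpy(dtype=float), y)
    presence, sign = _presence_sign(spec, est, X.shape[1])
    return TrainedModel(
        spec=spec,
        configuration=dict(configuration),
        estimator=est,
        feature_names=list(map(str, X.columns)),
        feature_presence=presence,
        feature_sign=sign,
    )


def _align(model: TrainedModel, X) -> np.ndarray:
    X = _to_frame(X)
    missing = [c for c in model.feature_names if c not in X.columns]
    if missing:
        raise ValueError(f"prediction data lacks model features: {missing[:5]}")
    return X.loc[:, model.feature_names].to_numpy(dtype=float)


def predict(model: TrainedModel, X) -> np.ndarray:
    """Predict labels (classification) or reals (regression), aligned by name."""
    return np.asarray(model.estimator.predict(_align(model, X)))


def decision_value(model: TrainedModel, X) -> Optional[np.ndarray]:
    """Continuous score for ROC curves (probability of the last class, or the
    decision function); None when the estimator exposes neither."""
    if model.spec.task != "classification":
        return None
    M = _align(model, X)
    est = model.estimator
    if hasattr(est, "predict_proba"):
        return np.asarray(est.predict_proba(M))[:, -1]
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(M))
    return None
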