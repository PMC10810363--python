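"""Grid-search hyperparameter tuning on nested resamples, with the 1SE rule.

Every configuration is scored on the SAME inner training/validation splits
(paired comparison; default tenfold cross-validation of the outer training
set). The best configuration optimises the mean validation score; the
one-standard-error (1SE) configuration is the simplest one -- per the learner's
declared complexity order -- whose mean lies within one standard error of the
optimum, trading a statistically indistinguishable loss for better expected
generalisation.

Tuning stability is also recorded: for the selected configuration, the
fraction of the m inner fits in which each feature was present.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .learners import LearnerSpec, TrainedModel, fit
from .metrics import MetricSpec, score_predictions
from .sampling import SamplingScheme, Split, draw_split, kfold_splits

__all__ = ["TuningResult", "grid_search", "one_se_config", "tuning_stability"]


@dataclass
class TuningResult:
    """Per-configuration resampled scores plus the two chosen configurations."""

    configurations: list[dict]
    mean_scores: np.ndarray  # NaN for dropped configurations
    std_errors: np.ndarray
    n_valid: np.ndarray  # inner scores that were defined, per configuration
    best_index: int
    one_se_index: int
    m: int  # inner fits of the selected configuration
    presence_counts: np.ndarray  # per feature, over those m fits
    split_digest: str = ""
    per_split_scores: Optional[np.ndarray] = None  # configs x inner splits

    @property
    def best_config(self) -> dict:
        return self.configurations[self.best_index]

    @property
    def one_se_config(self) -> dict:
        return self.configurations[self.one_se_index]


def _inner_splits(n_obs: int, scheme: SamplingScheme, rng: np.random.Generator) -> list[Split]:
    if scheme.scheme == "kfold":
        return kfold_splits(n_obs, scheme.k, strata=scheme.strata, rng=rng)
    # repeated subsample/bootstrap: k draws at a 3:1 train/validation ratio
    size = max(1, min(n_obs - 1, (3 * n_obs) // 4))
    return [
        draw_split(n_obs, size, scheme, rng, repeat_id=i) for i in range(scheme.k)
    ]


def _digest(splits: list[Split]) -> str:
    h = hashlib.sha256()
    for s in splits:
        h.update(np.asarray(s.train_idx, dtype=np.int64).tobytes())
        h.update(b"|")
        h.update(np.asarray(s.held_out_idx, dtype=np.int64).tobytes())
        h.update(b";")
    return h.hexdigest()[:16]


def one_se_config(
    config_scores: list[tuple[dict, float, float]],
    direction: str,
    complexity_key: Callable[[dict], tuple],
) -> dict:
    """Apply the one-standard-error rule to (config, mean, se) triples.

    Qualifying configurations have mean within best_mean +/- se_best on the
    favourable side (<= best+se when minimizing, >= best-se when maximizing);
    the SE is the optimum's own. Among them the one with the largest
    complexity key (the simplest) wins; exact key ties keep grid order.
    """
    finite = [(i, c, m, s) for i, (c, m, s) in enumerate(config_scores) if not math.isnan(m)]
    if not finite:
        raise ValueError("no configuration has a defined mean score")
    minimize = direction == "minimize"
    if minimize:
        bi = min(finite, key=lambda t: (t[2], t[0]))
    else:
        bi = max(finite, key=lambda t: (t[2], -t[0]))
    best_mean, best_se = bi[2], bi[3]
    if math.isnan(best_se):
        best_se = 0.0
    if minimize:
        qualify = [t for t in finite if t[2] <= best_mean + best_se]
    else:
        qualify = [t for t in finite if t[2] >= best_mean - best_se]
    chosen = max(qualify, key=lambda t: (complexity_key(t[1]), -t[0]))
    return chosen[1]


def grid_search(
    spec: LearnerSpec,
    X_train,
    y_train,
    inner_scheme: SamplingScheme,
    metric: MetricSpec,
    rng: np.random.Generator,
    positive=None,
    seed: Optional[int] = None,
    selection_rule: str = "best",
) -> TuningResult:
    """Score every grid configuration on identical inner splits.

    Undefined (NaN) validation scores are excluded from a configuration's mean
    with the valid count recorded; a configuration with no defined score is
    dropped (NaN mean) and logged. ``selection_rule`` decides which
    configuration's inner fits feed the presence counts ('best' or 'one_se').
    """
    import pandas as pd

    X = X_train if isinstance(X_train, pd.DataFrame) else pd.DataFrame(np.asarray(X_train))
    y = np.asarray(y_train)
    n = len(X)
    configs = spec.configurations()
    splits = _inner_splits(n, inner_scheme, rng)
    k = len(splits)

    scores = np.full((len(configs), k), np.nan)
    presence = np.zeros((len(configs), X.shape[1]), dtype=np.int64)
    fits = np.zeros(len(configs), dtype=np.int64)
    for ci, config in enumerate(configs):
        for si, sp in enumerate(splits):
            Xtr = X.iloc[sp.train_idx]
            ytr = y[sp.train_idx]
            Xva = X.iloc[sp.held_out_idx]
            yva = y[sp.held_out_idx]
            try:
                model = fit(spec, config, Xtr, ytr, seed=seed)
            except ValueError:
                continue  # e.g. single-class inner training set
            pred = model.predict(Xva)
            scores[ci, si] = score_predictions(yva, pred, metric, spec.task, positive)
            presence[ci] += model.feature_presence.astype(np.int64)
            fits[ci] += 1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n_valid = np.sum(~np.isnan(scores), axis=1)
        means = np.nanmean(np.where(np.isnan(scores), np.nan, scores), axis=1)
        sds = np.nanstd(scores, axis=1, ddof=1)
    means = np.where(n_valid == 0, np.nan, means)
    ses = np.where(n_valid >= 2, sds / np.sqrt(np.maximum(n_valid, 1)), 0.0)
    if (n_valid == 0).any():
        warnings.warn(
            f"{int((n_valid == 0).sum())} configuration(s) had no defined inner score and were dropped"
        )

    triples = [(c, float(means[i]), float(ses[i])) for i, c in enumerate(configs)]
    finite = [i for i in range(len(configs)) if not math.isnan(means[i])]
    if not finite:
        raise ValueError("every configuration failed during tuning")
    if metric.minimize:
        best_index = min(finite, key=lambda i: (means[i], i))
    else:
        best_index = max(finite, key=lambda i: (means[i], -i))
    one_se = one_se_config(triples, metric.direction, spec.complexity_key)
    one_se_index = configs.index(one_se)

    sel = best_index if selection_rule == "best" else one_se_index
    return TuningResult(
        configurations=configs,
        mean_scores=means,
        std_errors=ses,
        n_valid=n_valid,
        best_index=best_index,
        one_se_index=one_se_index,
        m=int(fits[sel]) if fits[sel] else k,
        presence_counts=presence[sel],
        split_digest=_digest(splits),
        per_split_scores=scores,
    )


def tuning_stability(result: TuningResult) -> np.ndarray:
    """Per-feature presence frequency across the m inner tuning fits."""
    if result.m < 1:
        raise ValueError("m must be >= 1")
    return result.presence_counts / result.m
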