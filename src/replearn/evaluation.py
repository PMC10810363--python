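"""The evaluation engine: repeated random sampling across training-set sizes.

For every training-set size in the grid and every repeat, the data are split
at random into independent training and held-out sets; supervised screening
(optional) and hyperparameter tuning see ONLY the training rows; the tuned
model is refit on the whole training split and scored on the training,
held-out (test) and full data. Per size, the n repeat scores give a sample
mean M_i, an unbiased sample SD s_i, the standard error of the mean
SEM_i = s_i / sqrt(n) and the confidence interval M_i +/- c * SEM_i, where c
is the Student-t quantile with n-1 degrees of freedom at the configured
confidence level (t rather than normal: conservative for small n, converging
to the normal value as n grows).

The overall best model is chosen in two stages on the test slice: first the
size with the most favourable CI bound (lowest upper bound for minimized
metrics, highest lower bound for maximized ones), then the single model with
the optimal test score at that size.

Each (size, repeat) task draws its randomness from a dedicated substream of
the master seed, so results are byte-identical regardless of how many workers
execute the embarrassingly parallel loop.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats

from .datasets import Dataset
from .learners import LearnerSpec, TrainedModel, fit
from .metrics import MetricSpec, get_metric, score_predictions
from .sampling import SamplingScheme, draw_split
from .screening import ScreenConfig, screen_features
from .tuning import grid_search, tuning_stability

__all__ = [
    "SizeGrid",
    "SizeSummary",
    "ModelRecord",
    "MethodEvaluation",
    "default_size_grid",
    "summarize_size",
    "evaluate_method",
    "select_best_model",
    "evaluate_model_external",
]

SLICES = ("train", "test", "full")


@dataclass(frozen=True)
class SizeGrid:
    """Training-set sizes to evaluate, each with the same number of repeats."""

    sizes: tuple
    n_repeats: int

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.sizes)
        object.__setattr__(self, "sizes", sizes)
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("sizes must be strictly increasing")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def default_size_grid(
    n_obs: int,
    n_sizes: int,
    min_size: Optional[int] = None,
    max_size: Optional[int] = None,
    n_repeats: int = 10,
) -> SizeGrid:
    """Evenly stepped size grid from half the data up to leave-one-out.

    Defaults: min_size = ceil(n_obs / 2), max_size = n_obs - 1. Intermediate
    sizes advance by the floor of the average step; the final element is
    always exactly max_size.
    """
    if n_sizes < 1:
        raise ValueError("n_sizes must be >= 1")
    lo = int(math.ceil(n_obs / 2)) if min_size is None else int(min_size)
    hi = (n_obs - 1) if max_size is None else int(max_size)
    if n_sizes == 1:
        return SizeGrid(sizes=(hi,), n_repeats=n_repeats)
    if hi <= lo:
        raise ValueError("max_size must exceed min_size for n_sizes > 1")
    step = (hi - lo) // (n_sizes - 1)
    sizes = [lo + i * step for i in range(n_sizes - 1)] + [hi]
    return SizeGrid(sizes=tuple(sizes), n_repeats=n_repeats)


@dataclass(frozen=True)
class SizeSummary:
    """Mean / SD / SEM / CI of the repeat scores at one training-set size."""

    mean: float
    sd: float
    sem: float
    ci_low: float
    ci_high: float
    confidence: float
    critical_value: float
    n: int
    n_undefined: int = 0


def summarize_size(performances, confidence: float = 0.95) -> SizeSummary:
    """Summarise the repeat scores of one size: M, s, SEM and the CI.

    NaN scores (undefined metrics or failed fits) are excluded and counted.
    With a single defined score the mean is reported and the CI flagged
    undefined (NaN bounds).
    """
    x = np.asarray(performances, dtype=float)
    if x.size == 0:
        raise ValueError("no performances to summarise")
    ok = ~np.isnan(x)
    n_undef = int((~ok).sum())
    x = x[ok]
    n = x.size
    if n == 0:
        return SizeSummary(math.nan, math.nan, math.nan, math.nan, math.nan,
                           confidence, math.nan, 0, n_undef)
    mean = float(np.mean(x))
    if n == 1:
        return SizeSummary(mean, math.nan, math.nan, math.nan, math.nan,
                           confidence, math.nan, 1, n_undef)
    sd = float(np.std(x, ddof=1))
    sem = sd / math.sqrt(n)
    c = float(stats.t.ppf(0.5 + confidence / 2, df=n - 1))
    return SizeSummary(
        mean=mean, sd=sd, sem=sem,
        ci_low=mean - c * sem, ci_high=mean + c * sem,
        confidence=confidence, critical_value=c, n=n, n_undefined=n_undef,
    )


@dataclass
class ModelRecord:
    """One fitted model within the evaluation: where it came from and how it did."""

    size_index: int
    size: int
    repeat_id: int
    configuration: dict
    selected_features: list[str]
    scores: dict  # slice -> metric name -> float (NaN = undefined)
    feature_presence: np.ndarray  # over the dataset's (post-filter) features
    feature_sign: np.ndarray
    feature_stability: np.ndarray
    train_idx: np.ndarray
    held_out_idx: np.ndarray
    failed: bool = False
    model: Optional[TrainedModel] = None  # in-memory only, not serialized

    def to_json_dict(self, feature_names: Sequence[str]) -> dict:
        nz = np.flatnonzero(self.feature_presence)
        return {
            "size_index": self.size_index,
            "size": self.size,
            "repeat_id": self.repeat_id,
            "configuration": self.configuration,
            "selected_features": list(self.selected_features),
            "scores": {
                sl: {m: _f(v) for m, v in ms.items()} for sl, ms in self.scores.items()
            },
            "present_features": {
                feature_names[i]: {
                    "sign": int(self.feature_sign[i]),
                    "stability": _f(float(self.feature_stability[i])),
                }
                for i in nz
            },
            # 1-based indices in all serialized output
            "train_idx": (self.train_idx + 1).tolist(),
            "held_out_idx": (self.held_out_idx + 1).tolist(),
            "failed": self.failed,
        }


def _f(v):
    """JSON-safe float (NaN -> None)."""
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def _unf(v):
    return math.nan if v is None else float(v)


@dataclass
class MethodEvaluation:
    """Container for one learning-method evaluation: records + summaries."""

    dataset_digest: str
    feature_names: list[str]
    config: dict
    records: list[ModelRecord]
    summaries: dict  # metric -> slice -> size -> SizeSummary
    sizes: tuple
    n_repeats: int
    metrics: list[str]

    # ---- selection ----------------------------------------------------
    def best_model(self, metric: Optional[str] = None) -> ModelRecord:
        return select_best_model(self, metric or self.metrics[0])

    # ---- tabular views -------------------------------------------------
    def summaries_frame(self) -> pd.DataFrame:
        rows = []
        for metric, slices in self.summaries.items():
            for sl, per_size in slices.items():
                for size, s in per_size.items():
                    rows.append({
                        "metric": metric, "slice": sl, "size": size,
                        "mean": s.mean, "sd": s.sd, "sem": s.sem,
                        "ci_low": s.ci_low, "ci_high": s.ci_high,
                        "confidence": s.confidence, "critical_value": s.critical_value,
                        "n": s.n, "n_undefined": s.n_undefined,
                    })
        return pd.DataFrame(rows)

    def models_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "size_index": r.size_index, "size": r.size, "repeat_id": r.repeat_id,
                "configuration": json.dumps(r.configuration, sort_keys=True),
                "n_selected_features": len(r.selected_features),
                "failed": r.failed,
            }
            for sl in SLICES:
                for m in self.metrics:
                    row[f"{sl}_{m}"] = r.scores.get(sl, {}).get(m, math.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    # ---- serialization -------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "dataset_digest": self.dataset_digest,
            "feature_names": self.feature_names,
            "config": self.config,
            "sizes": list(self.sizes),
            "n_repeats": self.n_repeats,
            "metrics": self.metrics,
            "records": [r.to_json_dict(self.feature_names) for r in self.records],
            "summaries": {
                metric: {
                    sl: {
                        str(size): {
                            "mean": _f(s.mean), "sd": _f(s.sd), "sem": _f(s.sem),
                            "ci_low": _f(s.ci_low), "ci_high": _f(s.ci_high),
                            "confidence": s.confidence,
                            "critical_value": _f(s.critical_value),
                            "n": s.n, "n_undefined": s.n_undefined,
                        }
                        for size, s in per_size.items()
                    }
                    for sl, per_size in slices.items()
                }
                for metric, slices in self.summaries.items()
            },
        }

    def save(self, out_dir) -> None:
        """Write evaluation.json, summaries.csv and models.csv."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "evaluation.json"), "w") as fh:
            json.dump(self.to_json_dict(), fh, sort_keys=True, indent=1)
        self.summaries_frame().to_csv(os.path.join(out_dir, "summaries.csv"), index=False)
        self.models_frame().to_csv(os.path.join(out_dir, "models.csv"), index=False)

    @classmethod
    def from_json_dict(cls, d: dict) -> "MethodEvaluation":
        feature_names = list(d["feature_names"])
        name_to_i = {n: i for i, n in enumerate(feature_names)}
        p = len(feature_names)
        records = []
        for rd in d["records"]:
            presence = np.zeros(p, dtype=np.int8)
            sign = np.zeros(p, dtype=np.int8)
            stability = np.zeros(p, dtype=float)
            for name, info in rd["present_features"].items():
                i = name_to_i[name]
                presence[i] = 1
                sign[i] = info["sign"]
                stability[i] = _unf(info["stability"])
            records.append(ModelRecord(
                size_index=rd["size_index"], size=rd["size"], repeat_id=rd["repeat_id"],
                configuration=rd["configuration"],
                selected_features=list(rd["selected_features"]),
                scores={sl: {m: _unf(v) for m, v in ms.items()}
                        for sl, ms in rd["scores"].items()},
                feature_presence=presence, feature_sign=sign,
                feature_stability=stability,
                train_idx=np.asarray(rd["train_idx"], dtype=np.intp) - 1,
                held_out_idx=np.asarray(rd["held_out_idx"], dtype=np.intp) - 1,
                failed=rd["failed"],
            ))
        summaries = {
            metric: {
                sl: {
                    int(size): SizeSummary(
                        mean=_unf(s["mean"]), sd=_unf(s["sd"]), sem=_unf(s["sem"]),
                        ci_low=_unf(s["ci_low"]), ci_high=_unf(s["ci_high"]),
                        confidence=s["confidence"],
                        critical_value=_unf(s["critical_value"]),
                        n=s["n"], n_undefined=s["n_undefined"],
                    )
                    for size, s in per_size.items()
                }
                for sl, per_size in slices.items()
            }
            for metric, slices in d["summaries"].items()
        }
        return cls(
            dataset_digest=d["dataset_digest"], feature_names=feature_names,
            config=d["config"], records=records, summaries=summaries,
            sizes=tuple(d["sizes"]), n_repeats=d["n_repeats"],
            metrics=list(d["metrics"]),
        )

    @classmethod
    def load(cls, path) -> "MethodEvaluation":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def _one_record(
    dataset: Dataset,
    spec: LearnerSpec,
    scheme: SamplingScheme,
    inner_scheme: SamplingScheme,
    metrics: list[MetricSpec],
    screen: Optional[ScreenConfig],
    size_index: int,
    size: int,
    repeat_id: int,
    seed_state: tuple,
    positive,
    selection_rule: str,
) -> ModelRecord:
    """Fit and score one (size, repeat) task on its own random substream."""
    ss = np.random.SeedSequence(entropy=seed_state[0], spawn_key=seed_state[1])
    split_ss, screen_ss, inner_ss, est_ss = ss.spawn(4)
    est_seed = int(est_ss.generate_state(1)[0] % (2**31))

    split = draw_split(dataset.n_obs, size, scheme, np.random.default_rng(split_ss),
                       repeat_id=repeat_id)
    # leakage guard: training and held-out rows must be disjoint
    assert np.intersect1d(np.unique(split.train_idx), split.held_out_idx).size == 0
    X, y = dataset.X, np.asarray(dataset.y)
    Xtr, ytr = X.iloc[split.train_idx], y[split.train_idx]

    p = dataset.n_features
    if screen is not None:
        sel = screen_features(Xtr.to_numpy(dtype=float), ytr, screen,
                              rng=np.random.default_rng(screen_ss))
    else:
        sel = np.arange(p)
    cols = X.columns[sel]
    primary = metrics[0]

    presence = np.zeros(p, dtype=np.int8)
    sign = np.zeros(p, dtype=np.int8)
    stability = np.zeros(p, dtype=float)
    scores: dict = {sl: {} for sl in SLICES}
    try:
        tune = grid_search(
            spec, Xtr[cols], ytr, inner_scheme, primary,
            np.random.default_rng(inner_ss), positive=positive, seed=est_seed,
            selection_rule=selection_rule,
        )
        config = tune.best_config if selection_rule == "best" else tune.one_se_config
        model = fit(spec, config, Xtr[cols], ytr, seed=est_seed)
    except ValueError:
        return ModelRecord(
            size_index=size_index, size=size, repeat_id=repeat_id,
            configuration={}, selected_features=[],
            scores={sl: {m.name: math.nan for m in metrics} for sl in SLICES},
            feature_presence=presence, feature_sign=sign, feature_stability=stability,
            train_idx=split.train_idx, held_out_idx=split.held_out_idx, failed=True,
        )

    presence[sel] = model.feature_presence
    sign[sel] = model.feature_sign
    stability[sel] = tuning_stability(tune)

    eval_rows = {
        "train": split.train_idx,
        "test": split.held_out_idx,
        "full": np.arange(dataset.n_obs),
    }
    for sl, rows in eval_rows.items():
        pred = model.predict(X.iloc[rows][cols])
        for m in metrics:
            scores[sl][m.name] = score_predictions(y[rows], pred, m, spec.task, positive)

    return ModelRecord(
        size_index=size_index, size=size, repeat_id=repeat_id,
        configuration=dict(config), selected_features=list(map(str, cols)),
        scores=scores, feature_presence=presence, feature_sign=sign,
        feature_stability=stability, train_idx=split.train_idx,
        held_out_idx=split.held_out_idx, failed=False, model=model,
    )


def evaluate_method(
    dataset: Dataset,
    spec: LearnerSpec,
    grid: SizeGrid,
    metric: MetricSpec | str,
    scheme: Optional[SamplingScheme] = None,
    inner_scheme: Optional[SamplingScheme] = None,
    screening: Optional[ScreenConfig] = None,
    extra_metrics: Sequence[MetricSpec | str] = (),
    confidence: float = 0.95,
    seed: int = 0,
    positive=None,
    selection_rule: str = "best",
    n_jobs: int = 1,
    keep_models: bool = True,
) -> MethodEvaluation:
    """Evaluate a learning methodology by repeated sampling across sizes.

    For each size in ``grid`` and each of the ``n_repeats`` repeats: draw a
    split, screen features on the training rows only, grid-search the
    hyperparameters on inner resamples, refit on the full training split and
    score on train / held-out / full data. Per-(size, repeat) substreams of
    ``seed`` make the run reproducible and independent of ``n_jobs``.
    """
    if scheme is None:
        scheme = SamplingScheme(scheme="subsample")
    if inner_scheme is None:
        inner_scheme = SamplingScheme(scheme="kfold", k=10)
    metrics = [get_metric(m) if isinstance(m, str) else m
               for m in [metric, *extra_metrics]]
    if max(grid.sizes) > dataset.n_obs - 1 and scheme.scheme == "subsample":
        raise ValueError("largest size must leave a non-empty held-out set")
    if screening is not None and spec.task != "classification":
        raise ValueError(
            "supervised screening is defined for classification responses only"
        )

    tasks = [
        (si, size, j)
        for si, size in enumerate(grid.sizes)
        for j in range(grid.n_repeats)
    ]
    results = Parallel(n_jobs=n_jobs)(
        delayed(_one_record)(
            dataset, spec, scheme, inner_scheme, metrics, screening,
            si, size, j, (seed, (si, j)), positive, selection_rule,
        )
        for si, size, j in tasks
    )
    if not keep_models:
        for r in results:
            r.model = None

    summaries: dict = {}
    for m in metrics:
        summaries[m.name] = {}
        for sl in SLICES:
            per_size = {}
            for si, size in enumerate(grid.sizes):
                vals = [
                    r.scores[sl].get(m.name, math.nan)
                    for r in results
                    if r.size_index == si and not r.failed
                ] or [math.nan]
                per_size[size] = summarize_size(vals, confidence)
            summaries[m.name][sl] = per_size

    n_failed = sum(r.failed for r in results)
    if n_failed:
        warnings.warn(f"{n_failed} model fit(s) failed and were excluded from summaries")

    config = {
        "learner": {"family": spec.family, "task": spec.task, "grid": spec.grid},
        "sampling": {"scheme": scheme.scheme, "allocation": scheme.allocation},
        "tuning": {"inner_scheme": inner_scheme.scheme, "inner_k": inner_scheme.k,
                   "rule": selection_rule},
        "screening": None if screening is None else {
            "method": screening.method, "alpha": screening.alpha,
            "top_k": screening.top_k, "permutations": screening.permutations,
        },
        "metric": metrics[0].name,
        "confidence": confidence,
        "seed": seed,
        "sizes": list(grid.sizes),
        "n_repeats": grid.n_repeats,
        "positive": None if positive is None else str(positive),
    }
    return MethodEvaluation(
        dataset_digest=dataset.digest(),
        feature_names=list(map(str, dataset.X.columns)),
        config=config,
        records=list(results),
        summaries=summaries,
        sizes=grid.sizes,
        n_repeats=grid.n_repeats,
        metrics=[m.name for m in metrics],
    )


def select_best_model(ev: MethodEvaluation, metric: MetricSpec | str) -> ModelRecord:
    """Two-stage best-model selection on the test slice.

    Stage 1: the size with the lowest CI upper bound (minimized metrics) or
    the highest CI lower bound (maximized). Stage 2: the record at that size
    with the optimal test score. Sizes whose CI is undefined fall back to
    comparing means; ties keep the smaller size.
    """
    m = get_metric(metric) if isinstance(metric, str) else metric
    per_size = ev.summaries[m.name]["test"]
    candidates = [(size, s) for size, s in per_size.items() if s.n >= 1]
    if not candidates:
        raise ValueError("no size has a defined test summary")

    def bound(item):
        size, s = item
        b = s.ci_high if m.minimize else s.ci_low
        if math.isnan(b):
            b = s.mean
        return (b if m.minimize else -b, size)

    best_size = min(candidates, key=bound)[0]
    recs = [r for r in ev.records if r.size == best_size and not r.failed
            and not math.isnan(r.scores["test"].get(m.name, math.nan))]
    if not recs:
        raise ValueError(f"no scored records at size {best_size}")
    key = lambda r: (r.scores["test"][m.name], r.repeat_id)
    return min(recs, key=key) if m.minimize else max(
        recs, key=lambda r: (r.scores["test"][m.name], -r.repeat_id)
    )


def evaluate_model_external(
    model: TrainedModel,
    X_ext,
    y_ext,
    metrics: Sequence[MetricSpec | str],
    positive=None,
) -> pd.DataFrame:
    """Score one fitted model on an external dataset; no refitting occurs."""
    specs = [get_metric(m) if isinstance(m, str) else m for m in metrics]
    pred = model.predict(X_ext)
    y = np.asarray(y_ext)
    rows = [{"metric": s.name,
             "value": score_predictions(y, pred, s, model.spec.task, positive)}
            for s in specs]
    return pd.DataFrame(rows)
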