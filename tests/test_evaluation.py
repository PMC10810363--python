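"""Size grids, per-size summaries, the evaluation engine and best-model rule."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import replearn as rl
from replearn.evaluation import (
    MethodEvaluation,
    ModelRecord,
    SizeGrid,
    default_size_grid,
    select_best_model,
    summarize_size,
)


# --------------------------------------------------------------- size grid

@pytest.mark.parametrize(
    "n_obs, n_sizes, kwargs, expected",
    [
        (343, 3, {}, (172, 257, 342)),
        (683, 5, {"max_size": 681}, (342, 426, 510, 594, 681)),
        (100, 1, {}, (99,)),
    ],
)
def test_default_size_grid(n_obs, n_sizes, kwargs, expected):
    assert default_size_grid(n_obs, n_sizes, **kwargs).sizes == expected


def test_size_grid_validation():
    with pytest.raises(ValueError):
        SizeGrid(sizes=(10, 10), n_repeats=2)
    with pytest.raises(ValueError):
        default_size_grid(100, 3, min_size=90, max_size=80)


# --------------------------------------------------------------- summaries

def test_summary_zero_variance():
    s = summarize_size([0.9, 0.9, 0.9])
    assert (s.mean, s.sem) == (0.9, 0.0)
    assert (s.ci_low, s.ci_high) == (0.9, 0.9)


def test_summary_two_values_against_hand_computation():
    s = summarize_size([0.8, 0.9], confidence=0.95)
    assert s.mean == pytest.approx(0.85)
    assert s.sd**2 == pytest.approx(0.005)
    assert s.sem == pytest.approx(0.05)
    # 97.5% Student-t quantile at 1 df, from standard tables
    assert s.critical_value == pytest.approx(12.7062047, rel=1e-6)
    assert s.ci_low == pytest.approx(0.85 - 12.7062047 * 0.05, rel=1e-6)


def test_summary_excludes_undefined_scores():
    s = summarize_size([0.5, math.nan, 0.7])
    assert s.n == 2 and s.n_undefined == 1
    assert s.mean == pytest.approx(0.6)


def test_summary_single_value_flags_undefined_ci():
    s = summarize_size([0.4])
    assert s.mean == 0.4 and math.isnan(s.ci_low)


def test_ci_coverage_quick():
    """The t-based CI covers a known Gaussian mean ~95% of the time (n=20)."""
    rng = np.random.default_rng(8)
    hits = 0
    reps = 2000
    for _ in range(reps):
        s = summarize_size(rng.normal(0.5, 0.1, size=20))
        hits += s.ci_low <= 0.5 <= s.ci_high
    assert hits / reps == pytest.approx(0.95, abs=0.02)


# --------------------------------------------------------------- engine

def test_degenerate_single_record(small_regression):
    ds, _ = small_regression
    spec = rl.LearnerSpec("glm_penalized", "regression",
                          {"alpha": [0.05], "l1_ratio": [1.0]})
    ev = rl.evaluate_method(ds, spec, SizeGrid(sizes=(60,), n_repeats=1), "mse", seed=1)
    assert len(ev.records) == 1
    rec = ev.records[0]
    assert ev.summaries["mse"]["test"][60].mean == pytest.approx(
        rec.scores["test"]["mse"]
    )


def test_record_leakage_and_score_slices(tiny_evaluation):
    ds, ev = tiny_evaluation
    assert len(ev.records) == len(ev.sizes) * ev.n_repeats
    for r in ev.records:
        # held-out rows never intersect the rows used for screening/tuning/fit
        assert np.intersect1d(r.train_idx, r.held_out_idx).size == 0
        assert len(r.train_idx) == r.size
        assert set(r.scores) == {"train", "test", "full"}


def test_summaries_recomputable_from_records(tiny_evaluation):
    _, ev = tiny_evaluation
    for size in ev.sizes:
        vals = [r.scores["test"]["mse"] for r in ev.records
                if r.size == size and not r.failed]
        s = summarize_size(vals, ev.config["confidence"])
        stored = ev.summaries["mse"]["test"][size]
        assert s.mean == stored.mean and s.sem == stored.sem
        assert s.ci_low == stored.ci_low and s.ci_high == stored.ci_high


def test_serialization_roundtrip(tiny_evaluation, tmp_path):
    _, ev = tiny_evaluation
    ev.save(tmp_path)
    loaded = MethodEvaluation.load(tmp_path / "evaluation.json")
    loaded.save(tmp_path / "again")
    assert (tmp_path / "evaluation.json").read_bytes() == (
        tmp_path / "again" / "evaluation.json"
    ).read_bytes()
    # serialized indices are 1-based
    d = json.loads((tmp_path / "evaluation.json").read_text())
    assert min(min(r["train_idx"]) for r in d["records"]) >= 1


# --------------------------------------------------------------- selection

def _fake_eval(rng, n_sizes=3, n_repeats=5, metric="mse"):
    sizes = tuple(sorted(rng.choice(np.arange(10, 500), n_sizes, replace=False)))
    records = []
    for si, size in enumerate(sizes):
        for j in range(n_repeats):
            records.append(ModelRecord(
                size_index=si, size=int(size), repeat_id=j, configuration={},
                selected_features=["f0"],
                scores={sl: {metric: float(rng.uniform(0, 1))}
                        for sl in ("train", "test", "full")},
                feature_presence=np.array([1], dtype=np.int8),
                feature_sign=np.array([1], dtype=np.int8),
                feature_stability=np.array([1.0]),
                train_idx=np.arange(size), held_out_idx=np.arange(size, size + 2),
            ))
    summaries = {metric: {}}
    for sl in ("train", "test", "full"):
        summaries[metric][sl] = {
            int(size): summarize_size(
                [r.scores[sl][metric] for r in records if r.size == size]
            )
            for size in sizes
        }
    return MethodEvaluation(
        dataset_digest="x", feature_names=["f0"], config={"confidence": 0.95},
        records=records, summaries=summaries, sizes=sizes,
        n_repeats=n_repeats, metrics=[metric],
    )


def test_select_best_model_rule_application(rng):
    ev = _fake_eval(rng)
    # overwrite test summaries with prescribed CI uppers: 0.30 vs 0.20 vs 0.50
    met = ev.metrics[0]
    uppers = {s: u for s, u in zip(ev.sizes, (0.30, 0.20, 0.50))}
    for size, s in ev.summaries[met]["test"].items():
        object.__setattr__(s, "ci_high", uppers[size])
    best = select_best_model(ev, met)
    assert best.size == ev.sizes[1]
    at_size = [r.scores["test"][met] for r in ev.records if r.size == ev.sizes[1]]
    assert best.scores["test"][met] == min(at_size)


def test_select_best_model_matches_brute_force_oracle(rng):
    """500 random CI/score tables against a two-stage argmin/argmax oracle."""
    for trial in range(500):
        metric = "mse" if trial % 2 == 0 else "acc"
        ev = _fake_eval(rng, n_sizes=int(rng.integers(1, 5)), metric=metric)
        got = select_best_model(ev, metric)
        minimize = metric == "mse"
        per_size = ev.summaries[metric]["test"]
        if minimize:
            size = min(ev.sizes, key=lambda s: (per_size[s].ci_high, s))
            want = min((r for r in ev.records if r.size == size),
                       key=lambda r: (r.scores["test"][metric], r.repeat_id))
        else:
            size = min(ev.sizes, key=lambda s: (-per_size[s].ci_low, s))
            want = max((r for r in ev.records if r.size == size),
                       key=lambda r: (r.scores["test"][metric], -r.repeat_id))
        assert got is want


def test_select_single_record_identity(rng):
    ev = _fake_eval(rng, n_sizes=1, n_repeats=1)
    assert select_best_model(ev, "mse") is ev.records[0]


# --------------------------------------------------------------- external

def test_external_evaluation_identity(small_regression):
    ds, _ = small_regression
    spec = rl.LearnerSpec("glm_penalized", "regression",
                          {"alpha": [0.05], "l1_ratio": [1.0]})
    ev = rl.evaluate_method(ds, spec, SizeGrid(sizes=(60,), n_repeats=1), "mse", seed=2)
    rec = ev.records[0]
    sub = ds.X.iloc[rec.train_idx][rec.selected_features]
    table = rl.evaluate_model_external(rec.model, sub, ds.y.iloc[rec.train_idx], ["mse"])
    assert table["value"][0] == pytest.approx(rec.scores["train"]["mse"])


def test_external_singleton_classification_accuracy_binary(small_classification):
    ds, _ = small_classification
    spec = rl.LearnerSpec("knn", "classification", {"n_neighbors": [3]})
    ev = rl.evaluate_method(ds, spec, SizeGrid(sizes=(70,), n_repeats=1), "err", seed=3)
    rec = ev.records[0]
    one = rl.evaluate_model_external(
        rec.model, ds.X.iloc[:1][rec.selected_features], ds.y.iloc[:1], ["acc"]
    )
    assert one["value"][0] in (0.0, 1.0)


def test_distribution_shift_degrades_external_scores():
    """External data from a shifted distribution scores worse than internal
    held-out data on average over seeds."""
    diffs = []
    for seed in range(20):
        ds, truth = rl.simulate_regression(n_obs=120, n_features=10, seed=seed)
        spec = rl.LearnerSpec("glm_penalized", "regression",
                              {"alpha": [0.05], "l1_ratio": [1.0]})
        ev = rl.evaluate_method(ds, spec, SizeGrid(sizes=(80,), n_repeats=1),
                                "mse", seed=seed)
        rec = ev.records[0]
        ext, _ = rl.simulate_regression(n_obs=120, n_features=10, seed=seed + 999)
        ext_X = ext.X + 1.5  # covariate shift away from the training support
        ext_y = (
            ext_X.to_numpy()[:, truth.informative] @ truth.coefficients
            + truth.noise_sd * np.random.default_rng(seed).standard_normal(len(ext_X))
        )
        t = rl.evaluate_model_external(rec.model, ext_X[rec.selected_features],
                                       ext_y, ["mse"])
        diffs.append(t["value"][0] - rec.scores["test"]["mse"])
    assert np.mean(diffs) > 0


def test_screening_requires_classification(small_regression):
    ds, _ = small_regression
    spec = rl.LearnerSpec("glm_penalized", "regression")
    with pytest.raises(ValueError, match="classification"):
        rl.evaluate_method(ds, spec, SizeGrid(sizes=(60,), n_repeats=1), "mse",
                           screening=rl.ScreenConfig(), seed=0)
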