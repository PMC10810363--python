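"""Classification/regression metric formulas against hand counts and a
brute-force per-observation oracle."""

import math

import numpy as np
import pytest

from replearn.metrics import (
    ConfusionMatrix,
    classification_score,
    confusion_matrix,
    get_metric,
    multiclass_average,
    regression_score,
    score_predictions,
)


@pytest.mark.parametrize(
    "y_true, y_pred, expected",
    [
        (list("++-"), list("++-"), (2, 0, 1, 0)),  # perfect prediction
        (list("+-"), list("-+"), (0, 1, 0, 1)),  # fully inverted
        (list("++---"), list("+-+--"), (1, 1, 2, 1)),  # hand count of five pairs
    ],
)
def test_confusion_matrix_counts(y_true, y_pred, expected):
    cm = confusion_matrix(y_true, y_pred, "+")
    assert (cm.tp, cm.fp, cm.tn, cm.fn) == expected
    assert cm.total == len(y_true)
    assert cm.p + cm.n_neg == cm.pp + cm.pn


def test_confusion_matrix_rejects_bad_input():
    with pytest.raises(ValueError):
        confusion_matrix(["+"], ["+", "-"], "+")
    with pytest.raises(ValueError):
        confusion_matrix([], [], "+")
    with pytest.raises(ValueError):
        confusion_matrix(["a", "b"], ["a", "b"], "+")


def test_classification_scores_perfect_and_mixed():
    perfect = ConfusionMatrix(tp=2, fp=0, tn=1, fn=0)
    assert classification_score(perfect, "acc") == 1
    assert classification_score(perfect, "err") == 0
    assert classification_score(perfect, "f1") == 1
    mixed = ConfusionMatrix(tp=1, fp=1, tn=2, fn=1)
    assert classification_score(mixed, "acc") == pytest.approx(3 / 5)
    assert classification_score(mixed, "precision") == pytest.approx(1 / 2)
    assert classification_score(mixed, "sensitivity") == pytest.approx(1 / 2)
    assert classification_score(mixed, "f1") == pytest.approx(1 / 2)


def test_undefined_scores_are_nan_not_zero():
    no_pp = ConfusionMatrix(tp=0, fp=0, tn=3, fn=2)  # nothing predicted positive
    assert math.isnan(classification_score(no_pp, "precision"))
    no_p = ConfusionMatrix(tp=0, fp=2, tn=3, fn=0)  # no actual positives
    assert math.isnan(classification_score(no_p, "sensitivity"))
    neither = ConfusionMatrix(tp=0, fp=0, tn=3, fn=0)
    assert math.isnan(classification_score(neither, "f1"))


def test_err_acc_complement_random_matrices(rng):
    for _ in range(100):
        cm = ConfusionMatrix(*(int(v) for v in rng.integers(0, 50, size=4)))
        if cm.total == 0:
            continue
        assert classification_score(cm, "err") + classification_score(cm, "acc") == 1


def test_f1_harmonic_mean_fixed_point():
    # precision == sensitivity == 0.5 => f1 == 0.5
    cm = ConfusionMatrix(tp=1, fp=1, tn=2, fn=1)
    assert classification_score(cm, "f1") == pytest.approx(
        classification_score(cm, "precision")
    )


def test_regression_identity_and_constant_predictions():
    assert regression_score([1, 2, 3], [1, 2, 3], "mse") == 0
    assert regression_score([1, 2, 3], [1, 2, 3], "r2") == 1
    assert regression_score([1, 2, 3], [2, 2, 2], "mse") == pytest.approx(2 / 3)
    assert regression_score([1, 2, 3], [2, 2, 2], "mae") == pytest.approx(2 / 3)
    assert regression_score([1, 2, 3], [2, 2, 2], "r2") == pytest.approx(0.0)


def test_mape_epsilon_branch():
    spec = get_metric("mape", epsilon=1e-8)
    assert regression_score([0.0], [1.0], spec) == pytest.approx(1e8)


def test_r2_nan_for_constant_truth():
    assert math.isnan(regression_score([2, 2, 2], [1, 2, 3], "r2"))


def test_rmse_squared_is_mse(rng):
    for _ in range(50):
        y = rng.normal(size=20)
        yh = rng.normal(size=20)
        assert regression_score(y, yh, "rmse") ** 2 == pytest.approx(
            regression_score(y, yh, "mse"), abs=1e-12
        )


@pytest.mark.parametrize(
    "scores, weights, expected",
    [([0.5, 0.5], None, 0.5), ([1.0, 0.0], [3, 1], 0.75), ([0.7], None, 0.7)],
)
def test_multiclass_average(scores, weights, expected):
    assert multiclass_average(scores, weights) == pytest.approx(expected)


def test_multiclass_average_empty_errors():
    with pytest.raises(ValueError):
        multiclass_average([])


def _brute_force(y_true, y_pred, name, positive=None, eps=1e-8):
    """Loop-based re-computation, independent of the vectorized path."""
    n = len(y_true)
    if name in ("mse", "rmse", "mae", "mape", "r2"):
        sq = ab = rel = 0.0
        for t, p in zip(y_true, y_pred):
            sq += (t - p) ** 2
            ab += abs(t - p)
            rel += abs(t - p) / max(abs(t), eps)
        if name == "mse":
            return sq / n
        if name == "rmse":
            return math.sqrt(sq / n)
        if name == "mae":
            return ab / n
        if name == "mape":
            return rel / n
        mean = sum(y_true) / n
        tot = sum((t - mean) ** 2 for t in y_true)
        return 1 - sq / tot
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive and p == positive:
            tp += 1
        elif t == positive:
            fn += 1
        elif p == positive:
            fp += 1
        else:
            tn += 1
    if name == "acc":
        return (tp + tn) / n
    if name == "err":
        return (fp + fn) / n
    if name == "precision":
        return tp / (tp + fp) if tp + fp else math.nan
    if name == "sensitivity":
        return tp / (tp + fn) if tp + fn else math.nan
    if name == "f1":
        d = tp + 0.5 * (fp + fn)
        return tp / d if d else math.nan
    raise AssertionError(name)


def test_all_metrics_match_brute_force_on_random_instances(rng):
    for _ in range(100):
        n = int(rng.integers(2, 30))
        yt = rng.normal(size=n)
        yp = rng.normal(size=n)
        for name in ("mse", "rmse", "mae", "mape"):
            assert regression_score(yt, yp, name) == pytest.approx(
                _brute_force(yt, yp, name), rel=1e-10
            )
        assert regression_score(yt, yp, "r2") == pytest.approx(
            _brute_force(yt, yp, "r2"), rel=1e-8
        )
        ct = rng.choice(["a", "b"], size=n)
        cp = rng.choice(["a", "b"], size=n)
        for name in ("acc", "err", "precision", "sensitivity", "f1"):
            got = classification_score(confusion_matrix(ct, cp, "b"), name)
            want = _brute_force(list(ct), list(cp), name, positive="b")
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, rel=1e-12)


def test_score_predictions_multiclass_macro_average():
    y = ["a", "a", "b", "b", "c", "c"]
    p = ["a", "b", "b", "b", "c", "a"]
    per_class = [
        classification_score(confusion_matrix(y, p, lab), "f1") for lab in "abc"
    ]
    assert score_predictions(y, p, "f1", "classification") == pytest.approx(
        np.nanmean(per_class)
    )


# ----------------------------------------------------------- property tests

from hypothesis import given, settings, strategies as st

counts = st.integers(min_value=0, max_value=1000)


@settings(deadline=None, derandomize=True)
@given(tp=counts, fp=counts, tn=counts, fn=counts)
def test_confusion_identities_hold_for_all_matrices(tp, fp, tn, fn):
    cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
    if cm.total == 0:
        return
    assert classification_score(cm, "err") + classification_score(cm, "acc") == 1
    f1 = classification_score(cm, "f1")
    prec = classification_score(cm, "precision")
    sens = classification_score(cm, "sensitivity")
    if not (math.isnan(f1) or math.isnan(prec) or math.isnan(sens)):
        # harmonic mean lies between its arguments
        assert min(prec, sens) - 1e-12 <= f1 <= max(prec, sens) + 1e-12
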