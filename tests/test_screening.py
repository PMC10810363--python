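"""Supervised screening: moderated t, permutation test, selection rules."""

import itertools
import math
import subprocess

import numpy as np
import pytest
from scipy import stats

import replearn as rl
from replearn.screening import (
    ScreenConfig,
    fit_variance_prior,
    moderated_t,
    permutation_test,
    screen_features,
    two_sample_t,
)


def _toy(rng, n=20, p=30, shift=0.0, n_shift=0):
    y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    X = rng.normal(size=(n, p))
    X[y == "b", :n_shift] += shift
    return X, y


def test_identical_groups_give_zero_statistic():
    base = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 15.0]])
    X = np.vstack([base, base])  # group b repeats group a exactly
    y = np.array(["a"] * 3 + ["b"] * 3)
    res = moderated_t(X, y)
    assert np.allclose(res.statistic, 0.0)


def test_d0_zero_recovers_classical_pooled_t(rng):
    X, y = _toy(rng, n=16, p=5)
    res = moderated_t(X, y, d0_override=0.0)
    # classical pooled two-sample t computed independently by formula
    A, B = X[y == "a"], X[y == "b"]
    n1, n2 = len(A), len(B)
    sp2 = (((A - A.mean(0)) ** 2).sum(0) + ((B - B.mean(0)) ** 2).sum(0)) / (n1 + n2 - 2)
    t = (A.mean(0) - B.mean(0)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    assert np.allclose(res.statistic, t)
    assert res.df_total == n1 + n2 - 2


def test_large_d0_pools_toward_prior_variance(rng):
    X, y = _toy(rng, n=20, p=50)
    res_inf = moderated_t(X, y, d0_override=math.inf)
    # with infinite prior df every feature shares one variance: statistics are
    # proportional to the raw mean differences
    A, B = X[y == "a"], X[y == "b"]
    diff = A.mean(0) - B.mean(0)
    ratio = res_inf.statistic / diff
    assert np.allclose(ratio, ratio[0])


def test_null_p_values_approximately_uniform():
    rng = np.random.default_rng(2024)
    X, y = _toy(rng, n=20, p=1000)
    res = moderated_t(X, y)
    frac = float(np.mean(res.p_value < 0.05))
    assert frac == pytest.approx(0.05, abs=0.02)
    # moderation should estimate a finite, positive prior on null data
    assert res.df_prior > 0


def test_variance_prior_moment_fit_recovers_simulated_prior():
    """Sample variances drawn from s0^2 * chi2_d/d scaled-F around a known prior."""
    rng = np.random.default_rng(7)
    d, d0, s0_2 = 18, 8.0, 2.0
    true_var = s0_2 * d0 / rng.chisquare(d0, size=5000)  # scaled inverse-chi2
    s2 = true_var * rng.chisquare(d, size=5000) / d
    d0_hat, s0_hat = fit_variance_prior(s2, d)
    assert d0_hat == pytest.approx(d0, rel=0.2)
    assert s0_hat == pytest.approx(s0_2, rel=0.1)


def test_moderated_t_matches_limma_oracle(tmp_path):
    """Cross-check statistic, p-value and the variance prior against
    Bioconductor limma on one simulated two-group matrix."""
    rng = np.random.default_rng(123)
    X, y = _toy(rng, n=16, p=40, shift=1.5, n_shift=4)
    mat = tmp_path / "mat.csv"
    np.savetxt(mat, X.T, delimiter=",")  # limma wants features x samples
    rcode = f"""
    suppressMessages(library(limma))
    x <- as.matrix(read.csv("{mat}", header=FALSE))
    grp <- factor(c(rep("a", 8), rep("b", 8)))
    design <- model.matrix(~grp)
    fit <- eBayes(lmFit(x, design))
    out <- cbind(fit$t[,2], fit$p.value[,2])
    write.csv(out, "{tmp_path}/limma.csv", row.names=FALSE)
    cat(fit$df.prior, fit$s2.prior)
    """
    proc = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True)
    assert proc.returncode == 0, proc.stderr
    ref = np.loadtxt(tmp_path / "limma.csv", delimiter=",", skiprows=1)
    d0_ref, s0_ref = (float(v) for v in proc.stdout.split())
    res = moderated_t(X, y)
    # limma's contrast is b - a; ours is a - b
    assert np.allclose(res.statistic, -ref[:, 0], rtol=1e-5)
    assert np.allclose(res.p_value, ref[:, 1], rtol=1e-5)
    assert res.df_prior == pytest.approx(d0_ref, rel=1e-4)
    assert res.var_prior == pytest.approx(s0_ref, rel=1e-4)


def test_group_size_validation():
    X = np.zeros((3, 2))
    with pytest.raises(ValueError):
        moderated_t(X, np.array(["a", "a", "b"]))  # group b has 1 member
    with pytest.raises(ValueError):
        moderated_t(np.zeros((4, 2)), np.array(["a"] * 4))


def test_all_zero_variance_prior_inestimable():
    X = np.ones((6, 3))
    y = np.array(["a"] * 3 + ["b"] * 3)
    with pytest.raises(ValueError):
        moderated_t(X, y)


# ---------------------------------------------------------------- permutation

def test_permutation_add_one_bound():
    """Observed statistic strictly above every permuted value: p = 1/(B+1)."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(20, 1))
    y = np.array(["a"] * 10 + ["b"] * 10)
    y_obs = y.copy()

    def stat(_X, yy):
        return np.array([1.0 if np.array_equal(yy, y_obs) else 0.0])

    res = permutation_test(X, y, base_statistic=stat, B=999,
                           rng=np.random.default_rng(1))
    assert res.p_value[0] == pytest.approx(1 / 1000)


def test_permutation_null_centre_p_is_one():
    X = np.random.default_rng(0).normal(size=(10, 1))
    y = np.array(["a", "b"] * 5)
    res = permutation_test(X, y, base_statistic=lambda _X, _y: np.array([0.0]),
                           B=99, rng=np.random.default_rng(2))
    assert res.p_value[0] == 1.0


def test_exhaustive_permutation_matches_full_enumeration():
    """6-sample two-group toy: exhaustive p equals an independent enumeration."""
    rng = np.random.default_rng(5)
    X = rng.normal(size=(6, 3))
    X[3:, 0] += 3.0
    y = np.array(["a", "a", "a", "b", "b", "b"])
    res = permutation_test(X, y, exhaustive=True)

    # independent oracle: enumerate all 20 assignments of 3 'b' labels
    obs = np.abs(two_sample_t(X, y))
    count = np.zeros(3)
    total = 0
    for pos in itertools.combinations(range(6), 3):
        yp = np.array(["a"] * 6)
        yp[list(pos)] = "b"
        count += np.abs(two_sample_t(X, yp)) >= obs - 1e-12
        total += 1
    assert total == 20
    assert np.allclose(res.p_value, count / total)


def test_permutation_p_values_are_valid_under_null():
    rng = np.random.default_rng(11)
    X, y = _toy(rng, n=20, p=500)
    res = permutation_test(X, y, B=99, rng=rng)
    for alpha in (0.01, 0.05, 0.1):
        assert np.mean(res.p_value <= alpha) <= alpha + 0.03


def test_permutation_rejects_constant_response():
    with pytest.raises(ValueError):
        permutation_test(np.zeros((4, 1)), np.array(["a"] * 4), B=10)


# ---------------------------------------------------------------- selection

def test_alpha_one_selects_everything(rng):
    X, y = _toy(rng, n=20, p=15)
    sel = screen_features(X, y, ScreenConfig(method="moderated_t", alpha=1.0))
    assert sel.tolist() == list(range(15))


def test_informative_features_recovered():
    """5 informative of 100 at effect 2 SD, n=100: top-5 capture the truth
    in at least 95 of 100 simulations."""
    hits = 0
    for s in range(100):
        rng = np.random.default_rng(1000 + s)
        X, y = _toy(rng, n=100, p=100, shift=2.0, n_shift=5)
        sel = screen_features(X, y, ScreenConfig(method="moderated_t",
                                                 alpha=0.05, top_k=5))
        if set(sel) == set(range(5)):
            hits += 1
    assert hits >= 95


def test_both_tests_intersect():
    rng = np.random.default_rng(3)
    X, y = _toy(rng, n=30, p=20, shift=3.0, n_shift=3)
    cfg_b = ScreenConfig(method="both", alpha=0.05, permutations=199)
    sel_both = screen_features(X, y, cfg_b, rng=np.random.default_rng(4))
    sel_t = screen_features(X, y, ScreenConfig(method="moderated_t", alpha=0.05))
    sel_p = screen_features(X, y, ScreenConfig(method="permutation", alpha=0.05,
                                               permutations=199),
                            rng=np.random.default_rng(4))
    assert set(sel_both) <= set(sel_t)
    assert set(sel_both) <= set(sel_p)


def test_empty_selection_falls_back_with_warning(rng):
    X, y = _toy(rng, n=20, p=10)  # pure noise
    with pytest.warns(UserWarning, match="no features"):
        sel = screen_features(X, y, ScreenConfig(method="moderated_t", alpha=1e-12))
    assert len(sel) == 1


def test_screening_ignores_held_out_rows(rng):
    """Selection is a function of the training rows alone: changing what
    would be held-out data cannot alter it."""
    X, y = _toy(rng, n=40, p=25, shift=2.5, n_shift=3)
    train = np.arange(30)
    cfg = ScreenConfig(method="moderated_t", alpha=0.05)
    sel_a = screen_features(X[train], y[train], cfg)
    X2 = X.copy()
    X2[30:] = 1e6  # arbitrary junk in the held-out rows
    sel_b = screen_features(X2[train], y[train], cfg)
    assert np.array_equal(sel_a, sel_b)
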