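"""Supervised feature screening, run inside each training split.

Two tests are offered for two-group (binary response) problems:

* **Empirical-Bayes moderated t** -- a two-sample t-statistic whose per-feature
  variance estimate is shrunk toward a common prior. The per-feature sample
  variances s_g^2 (pooled, d residual df each) are modelled as scaled-F draws
  around a prior s0^2 with d0 prior df; (d0, s0^2) are estimated by moment
  matching on log s_g^2 (digamma/trigamma matching). The moderated statistic
  uses the posterior variance s~^2 = (d0 s0^2 + d s^2)/(d0 + d) and is referred
  to a t-distribution with d + d0 degrees of freedom. With d0 = 0 it reduces to
  the classical pooled t; as d0 -> infinity every feature is tested against the
  common prior variance.

* **Permutation test** -- the response labels are permuted, features fixed; the
  two-sided p-value is the add-one estimator (1 + #{|stat_b| >= |stat_obs|}) /
  (B + 1), or the exact enumeration fraction when all distinct label
  assignments are requested.

Screening is leakage-safe by construction: callers hand in training rows only,
and the evaluation engine never lets these functions see held-out data.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import special, stats

__all__ = [
    "ScreeningResult",
    "ScreenConfig",
    "moderated_t",
    "permutation_test",
    "screen_features",
    "fit_variance_prior",
    "two_sample_t",
]


@dataclass
class ScreeningResult:
    """Per-feature statistics, p-values and the selected feature indices."""

    statistic: np.ndarray
    p_value: np.ndarray
    selected: np.ndarray
    method: str
    df_prior: float = math.nan  # d0 (moderated t only)
    var_prior: float = math.nan  # s0^2 (moderated t only)
    df_total: float = math.nan  # d + d0 (moderated t only)


@dataclass(frozen=True)
class ScreenConfig:
    """Selection rule: which test(s), the p cutoff, the feature cap.

    ``method`` is ``moderated_t``, ``permutation`` or ``both`` (intersection of
    the two selections). Features with p < ``alpha`` are selected, capped at the
    ``top_k`` smallest p-values; if nothing passes, the ``fallback_k`` features
    with largest |statistic| are taken instead so a model can always be fit.
    """

    method: str = "moderated_t"
    alpha: float = 0.05
    top_k: int = 500
    permutations: int = 1000
    fallback_k: int = 1


def _group_arrays(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.unique(y)
    if len(groups) != 2:
        raise ValueError("screening tests require exactly two groups")
    A = X[y == groups[0]]
    B = X[y == groups[1]]
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each group needs at least 2 observations")
    return A, B


def two_sample_t(X, y) -> np.ndarray:
    """Classical pooled two-sample t per feature (mean(A) - mean(B))."""
    A, B = _group_arrays(X, y)
    n1, n2 = len(A), len(B)
    s2 = _pooled_variance(A, B)
    se = np.sqrt(s2 * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (A.mean(axis=0) - B.mean(axis=0)) / se
    return np.where(se == 0, 0.0, t)


def _pooled_variance(A, B) -> np.ndarray:
    n1, n2 = len(A), len(B)
    ss = ((A - A.mean(axis=0)) ** 2).sum(axis=0) + ((B - B.mean(axis=0)) ** 2).sum(axis=0)
    return ss / (n1 + n2 - 2)


def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration on 1/y scale."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) / y < tol:
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate the prior df d0 and prior variance s0^2 by moment matching.

    Models s2 ~ s0^2 * F(df, d0). On the log scale, z = log(s2) has
    E z = log(s0^2) + digamma(df/2) - log(df/2) - digamma(d0/2) + log(d0/2)
    and Var z = trigamma(df/2) + trigamma(d0/2); solving the excess variance
    for d0 uses a Newton trigamma inverse. Returns (inf, exp(mean)) when the
    observed variance of z does not exceed trigamma(df/2) (no evidence of
    variance heterogeneity) and raises if every variance is zero.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all pooled variances are zero; prior inestimable")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + math.log(df / 2)
    emean = float(np.mean(e))
    if len(z) < 2:
        return math.inf, math.exp(emean)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2))
    if evar <= 0:
        return math.inf, math.exp(emean)
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_2 = math.exp(
        emean + float(special.digamma(d0 / 2)) - math.log(d0 / 2)
    )
    return d0, s0_2


def moderated_t(
    X_train,
    y_train,
    alpha: float = 0.05,
    d0_override: Optional[float] = None,
) -> ScreeningResult:
    """Empirical-Bayes moderated two-sample t-test per feature.

    Returns statistics, two-sided p-values from t with d + d0 df, and the
    indices with p < alpha. ``d0_override`` pins the prior df (0 recovers the
    classical pooled t) and is mainly for validation.
    """
    A, B = _group_arrays(np.asarray(X_train, dtype=float), y_train)
    n1, n2 = len(A), len(B)
    df = n1 + n2 - 2
    s2 = _pooled_variance(A, B)
    if d0_override is not None and d0_override == 0:
        d0, s0_2 = 0.0, math.nan  # classical pooled t, prior unused
    else:
        d0, s0_2 = fit_variance_prior(s2, df)
        if d0_override is not None:
            d0 = float(d0_override)
    if math.isinf(d0):
        s_tilde2 = np.full_like(s2, s0_2)
        df_total = math.inf
    elif d0 == 0:
        s_tilde2 = s2
        df_total = float(df)
    else:
        s_tilde2 = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = df + d0
    se = np.sqrt(s_tilde2 * (1 / n1 + 1 / n2))
    diff = A.mean(axis=0) - B.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t = np.where(se == 0, 0.0, t)
    if math.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    selected = np.flatnonzero(p < alpha)
    return ScreeningResult(
        statistic=t,
        p_value=p,
        selected=selected,
        method="moderated_t",
        df_prior=d0,
        var_prior=s0_2,
        df_total=df_total,
    )


def permutation_test(
    X_train,
    y_train,
    base_statistic: Optional[Callable] = None,
    B: int = 1000,
    rng: Optional[np.random.Generator] = None,
    alpha: float = 0.05,
    exhaustive: bool = False,
) -> ScreeningResult:
    """Label-permutation test of per-feature association with a binary response.

    ``base_statistic(X, y)`` maps a matrix and labels to one statistic per
    feature (default: classical pooled two-sample t). In sampled mode the
    two-sided p-value is (1 + #{|stat_b| >= |stat_obs|}) / (B + 1); in
    exhaustive mode all distinct label assignments are enumerated and the
    p-value is the exact fraction (the identity assignment makes it > 0).
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    if len(np.unique(y)) < 2:
        raise ValueError("constant response; permutation test undefined")
    if base_statistic is None:
        base_statistic = two_sample_t
    stat_obs = np.abs(np.asarray(base_statistic(X, y), dtype=float))
    n = len(y)
    if exhaustive:
        groups, inverse = np.unique(y, return_inverse=True)
        n_pos = int(np.sum(inverse == 1))
        exceed = np.zeros_like(stat_obs)
        total = 0
        for pos in itertools.combinations(range(n), n_pos):
            y_perm = np.full(n, groups[0], dtype=y.dtype)
            y_perm[list(pos)] = groups[1]
            sb = np.abs(np.asarray(base_statistic(X, y_perm), dtype=float))
            exceed += sb >= stat_obs - 1e-12
            total += 1
        p = exceed / total
    else:
        if B < 1:
            raise ValueError("B must be >= 1")
        if rng is None:
            rng = np.random.default_rng()
        exceed = np.zeros_like(stat_obs)
        for _ in range(B):
            y_perm = rng.permutation(y)
            sb = np.abs(np.asarray(base_statistic(X, y_perm), dtype=float))
            exceed += sb >= stat_obs - 1e-12
        p = (1.0 + exceed) / (B + 1.0)
    selected = np.flatnonzero(p < alpha)
    return ScreeningResult(
        statistic=np.asarray(base_statistic(X, y), dtype=float),
        p_value=p,
        selected=selected,
        method="permutation",
    )


def _select(result: ScreeningResult, config: ScreenConfig) -> np.ndarray:
    sel = np.flatnonzero(result.p_value < config.alpha)
    if len(sel) > config.top_k:
        order = np.argsort(result.p_value[sel], kind="stable")
        sel = np.sort(sel[order[: config.top_k]])
    return sel


def screen_features(
    X_train,
    y_train,
    config: ScreenConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Run the configured screening test(s) on one training split.

    Multiclass responses are screened one-vs-rest with the minimum p per
    feature. When both tests are requested, the selections are intersected.
    An empty selection falls back to the ``fallback_k`` smallest p-values
    (logged as a warning) so downstream fitting never receives zero features.
    Returns selected feature indices in the caller's (post-filter) space.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    classes = np.unique(y)

    def run(method: str) -> ScreeningResult:
        def one(yb) -> ScreeningResult:
            if method == "moderated_t":
                return moderated_t(X, yb, alpha=config.alpha)
            return permutation_test(
                X, yb, B=config.permutations, rng=rng, alpha=config.alpha
            )

        if len(classes) == 2:
            return one(y)
        # one-vs-rest; keep the strongest (minimum-p) evidence per feature
        best = None
        for c in classes:
            res = one(np.where(y == c, "pos", "rest"))
            if best is None:
                best = res
            else:
                take = res.p_value < best.p_value
                best.p_value = np.where(take, res.p_value, best.p_value)
                best.statistic = np.where(take, res.statistic, best.statistic)
        best.selected = np.flatnonzero(best.p_value < config.alpha)
        return best

    if config.method == "both":
        sel_t = _select(run("moderated_t"), config)
        sel_p = _select(run("permutation"), config)
        selected = np.intersect1d(sel_t, sel_p)
        ref = run("moderated_t")
    else:
        ref = run(config.method)
        selected = _select(ref, config)
    if len(selected) == 0:
        warnings.warn(
            "screening selected no features; falling back to smallest p-values"
        )
        order = np.argsort(ref.p_value, kind="stable")
        selected = np.sort(order[: config.fallback_k])
    return np.asarray(selected, dtype=np.intp)
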