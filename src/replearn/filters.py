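"""Unsupervised feature screening, applied once before any sampling.

Three response-blind rules: (i) missing-value ratio, (ii) threshold-based
selection (a feature must exceed a threshold -- fixed, or each sample's own
median across features -- in enough samples), and (iii) variability-based
selection keeping the most variable features by SD, IQR or MAD.

None of these functions accept the response vector: that is the leakage guard.
Missing values (NaN) are ignored pairwise when computing variability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilterRule",
    "filter_missing_ratio",
    "filter_threshold",
    "filter_variability",
    "apply_filters",
]

#: consistency constant making MAD estimate the SD under normality
MAD_SCALE = 1.4826


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


@dataclass(frozen=True)
class FilterRule:
    """Declarative form of one filtering rule (for configs)."""

    kind: str  # missing_ratio | threshold | variability
    cutoff: Optional[float] = None  # missing_ratio cutoff or threshold value
    min_samples: Union[int, float] = 0.5  # threshold rule; fraction or count
    measure: str = "sd"  # variability rule
    keep: Union[int, float] = 1.0  # variability rule; fraction or count
    per_sample_median: bool = False  # threshold rule


def filter_missing_ratio(X, cutoff: float) -> np.ndarray:
    """Keep features whose fraction of missing values is <= cutoff."""
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must be in [0, 1]")
    M = _as_matrix(X)
    ratio = np.isnan(M).mean(axis=0)
    mask = ratio <= cutoff
    if not mask.any():
        warnings.warn("missing-ratio filter removed every feature")
    return mask


def filter_threshold(
    X,
    threshold: Union[float, str] = "median",
    min_samples: Union[int, float] = 0.5,
) -> np.ndarray:
    """Keep features that strictly exceed a threshold in enough samples.

    ``threshold`` is either a fixed value or ``"median"``, in which case each
    value is compared against its own sample's median across features (the
    usual minimal-expression rule for gene expression matrices). ``min_samples``
    is an absolute count (int) or a fraction of samples (float in (0, 1]);
    equality with the threshold counts as failing. All-missing features fail.
    """
    M = _as_matrix(X)
    n_obs = M.shape[0]
    if isinstance(min_samples, float) and 0 < min_samples <= 1:
        required = int(math.ceil(min_samples * n_obs))
    else:
        required = int(min_samples)
    if required > n_obs:
        raise ValueError("min_samples exceeds the number of samples")
    if isinstance(threshold, str):
        if threshold != "median":
            raise ValueError("threshold must be a number or 'median'")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ref = np.nanmedian(M, axis=1, keepdims=True)
        exceeds = M > ref
    else:
        exceeds = M > float(threshold)
    exceeds = np.where(np.isnan(M), False, exceeds)
    return exceeds.sum(axis=0) >= required


def _variability(M: np.ndarray, measure: str, mad_scale: float) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if measure == "sd":
            return np.nanstd(M, axis=0, ddof=1)
        if measure == "iqr":
            q75, q25 = np.nanpercentile(M, [75, 25], axis=0)
            return q75 - q25
        if measure == "mad":
            med = np.nanmedian(M, axis=0, keepdims=True)
            return mad_scale * np.nanmedian(np.abs(M - med), axis=0)
    raise ValueError(f"unknown variability measure {measure!r}")


def filter_variability(
    X,
    measure: str = "sd",
    keep: Union[int, float] = 1.0,
    mad_scale: float = MAD_SCALE,
) -> np.ndarray:
    """Keep the most variable features by SD, IQR or (scaled) MAD.

    ``keep`` is a fraction in (0, 1] (rounded up to ceil(keep * p) features)
    or an absolute count. Ties and the ranking itself break deterministically
    by feature order. Constant features have measure 0 and rank last.
    """
    M = _as_matrix(X)
    p = M.shape[1]
    if p == 0:
        raise ValueError("no features")
    if isinstance(keep, float):
        if not 0 < keep <= 1:
            raise ValueError("keep fraction must be in (0, 1]")
        n_keep = int(math.ceil(keep * p))
    else:
        n_keep = int(keep)
        if not 1 <= n_keep <= p:
            raise ValueError("keep count out of range")
    v = _variability(M, measure, mad_scale)
    v = np.where(np.isnan(v), -np.inf, v)  # all-missing features rank last
    order = np.argsort(-v, kind="stable")  # stable => ties by feature order
    mask = np.zeros(p, dtype=bool)
    mask[order[:n_keep]] = True
    return mask


def apply_filters(X: pd.DataFrame, rules: list[FilterRule]) -> np.ndarray:
    """Apply rules in order; a feature must survive every rule. Returns a mask
    over the original feature axis."""
    mask = np.ones(X.shape[1], dtype=bool)
    current = X
    for rule in rules:
        if rule.kind == "missing_ratio":
            sub = filter_missing_ratio(current, rule.cutoff)
        elif rule.kind == "threshold":
            thr = "median" if rule.per_sample_median else rule.cutoff
            sub = filter_threshold(current, thr, rule.min_samples)
        elif rule.kind == "variability":
            sub = filter_variability(current, rule.measure, rule.keep)
        else:
            raise ValueError(f"unknown filter rule {rule.kind!r}")
        idx = np.flatnonzero(mask)
        mask[idx[~sub]] = False
        current = X.iloc[:, np.flatnonzero(mask)] if isinstance(X, pd.DataFrame) else X[:, mask]
    return mask
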