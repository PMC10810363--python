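"""Random partitioning of observations into training and held-out sets.

Three schemes: sampling without replacement (``subsample``), sampling with
replacement (``bootstrap``, held-out = out-of-bag complement), and k-fold
cross-validation. With a stratification variable, per-stratum counts follow
proportionate allocation (strata proportions preserved, largest-remainder
rounding) or balanced allocation (strata counts equalised).

Indices are 0-based in memory; serialized exports are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Split",
    "SamplingScheme",
    "stratified_allocation",
    "draw_split",
    "kfold_splits",
    "export_splits",
]

SCHEMES = ("subsample", "bootstrap", "kfold")


@dataclass(frozen=True)
class Split:
    """One training / held-out partition of the observation indices."""

    train_idx: np.ndarray
    held_out_idx: np.ndarray
    size_requested: int
    scheme: str
    repeat_id: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "train_idx", np.asarray(self.train_idx, dtype=np.intp))
        object.__setattr__(
            self, "held_out_idx", np.asarray(self.held_out_idx, dtype=np.intp)
        )

    def validate(self, n_obs: int) -> None:
        train = self.train_idx
        held = self.held_out_idx
        if self.scheme in ("subsample", "kfold"):
            if len(np.unique(train)) != len(train):
                raise AssertionError("duplicate training indices")
        if np.intersect1d(np.unique(train), held).size:
            raise AssertionError("train/held-out overlap")
        expected_held = np.setdiff1d(np.arange(n_obs), np.unique(train))
        if not np.array_equal(np.sort(held), expected_held):
            raise AssertionError("held-out is not the complement of training")


@dataclass(frozen=True)
class SamplingScheme:
    """How to draw splits: scheme, optional strata, allocation mode, k."""

    scheme: str = "subsample"
    strata: Optional[np.ndarray] = None
    allocation: str = "none"
    k: int = 10

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.allocation not in ("proportionate", "balanced", "none"):
            raise ValueError(f"unknown allocation {self.allocation!r}")
        if self.allocation == "balanced" and self.scheme == "kfold":
            raise ValueError("balanced allocation applies to subsample/bootstrap only")
        if self.strata is not None:
            object.__setattr__(self, "strata", np.asarray(self.strata))


def stratified_allocation(
    strata_counts: dict, size: int, mode: str, strict: bool = False
) -> dict:
    """Allocate ``size`` draws across strata.

    ``proportionate``: quotas size*count/total rounded by the largest-remainder
    method (ties broken by stratum order as given). ``balanced``: start from
    floor(size/#strata) each, then hand the remainder to strata in decreasing
    availability order; counts are capped at availability with the excess
    redistributed, and it is an error if availability cannot cover ``size``.
    The allocated counts always sum exactly to ``size``.

    With ``strict`` (used for balanced sampling without replacement), a
    stratum unable to supply its balanced share is an error rather than a
    silent cap-and-redistribute.
    """
    labels = list(strata_counts)
    counts = np.array([strata_counts[l] for l in labels], dtype=float)
    if (counts < 1).any():
        raise ValueError("every stratum must have at least one observation")
    total = counts.sum()
    if size < 0:
        raise ValueError("size must be non-negative")
    if mode == "proportionate":
        if size > total:
            raise ValueError("size exceeds the number of observations")
        quota = size * counts / total
        alloc = np.floor(quota).astype(int)
        remainder = quota - alloc
        short = size - alloc.sum()
        # largest remainders first; ties by stratum order (stable sort on -rem)
        order = np.argsort(-remainder, kind="stable")
        for idx in order[:short]:
            alloc[idx] += 1
        # cap by availability (can only trigger with non-integer edge cases)
        for i in np.argsort(-remainder, kind="stable"):
            over = alloc[i] - int(counts[i])
            if over > 0:
                alloc[i] -= over
                for j in order:
                    room = int(counts[j]) - alloc[j]
                    if room > 0:
                        give = min(room, over)
                        alloc[j] += give
                        over -= give
                        if over == 0:
                            break
    elif mode == "balanced":
        if size > total:
            raise ValueError("size exceeds the number of observations")
        g = len(labels)
        alloc = np.full(g, size // g, dtype=int)
        rem = size - alloc.sum()
        by_avail = np.argsort(-counts, kind="stable")
        for idx in by_avail[:rem]:
            alloc[idx] += 1
        # respect availability; push the overflow to the strata with room
        deficit = 0
        for i in range(g):
            over = alloc[i] - int(counts[i])
            if over > 0:
                if strict:
                    raise ValueError(
                        f"stratum {labels[i]!r} cannot supply its balanced share "
                        f"({alloc[i]} requested, {int(counts[i])} available)"
                    )
                alloc[i] = int(counts[i])
                deficit += over
        while deficit > 0:
            room = np.array([int(c) - a for c, a in zip(counts, alloc)])
            if room.max() <= 0:
                raise ValueError("size exceeds total availability across strata")
            idx = int(np.argmax(room))
            alloc[idx] += 1
            deficit -= 1
    else:
        raise ValueError(f"unknown allocation mode {mode!r}")
    assert alloc.sum() == size
    return {l: int(a) for l, a in zip(labels, alloc)}


def _strata_groups(strata: np.ndarray) -> dict:
    labels, inverse = np.unique(strata, return_inverse=True)
    return {lab: np.flatnonzero(inverse == i) for i, lab in enumerate(labels)}


def draw_split(
    n_obs: int,
    size: int,
    scheme: SamplingScheme,
    rng: np.random.Generator,
    repeat_id: int = 0,
) -> Split:
    """Draw one random training/held-out split of ``n_obs`` observations.

    Without replacement the training set holds ``size`` unique indices and the
    held-out set is its complement (required non-empty, so size <= n_obs-1).
    Bootstrap draws ``size`` indices with replacement; the held-out set is the
    out-of-bag complement of the distinct training indices.
    """
    if scheme.scheme == "kfold":
        raise ValueError("use kfold_splits for the kfold scheme")
    replace = scheme.scheme == "bootstrap"
    if size < 1:
        raise ValueError("size must be >= 1")
    if not replace and size > n_obs - 1:
        raise ValueError("without replacement, size must leave a non-empty held-out set")
    if replace and size > n_obs:
        raise ValueError("bootstrap size must not exceed n_obs")

    if scheme.strata is not None and scheme.allocation != "none":
        strata = np.asarray(scheme.strata)
        if len(strata) != n_obs:
            raise ValueError("strata length must equal n_obs")
        groups = _strata_groups(strata)
        counts = {lab: len(idx) for lab, idx in groups.items()}
        alloc = stratified_allocation(
            counts, size, scheme.allocation, strict=not replace
        )
        parts = []
        for lab, idx in groups.items():
            take = alloc[lab]
            if not replace and take > len(idx):
                raise ValueError(
                    f"stratum {lab!r} has {len(idx)} observations, {take} requested"
                )
            if take:
                parts.append(rng.choice(idx, size=take, replace=replace))
        train = np.concatenate(parts) if parts else np.empty(0, dtype=np.intp)
        train = np.sort(train) if not replace else train
    else:
        train = rng.choice(n_obs, size=size, replace=replace)
        if not replace:
            train = np.sort(train)
    held = np.setdiff1d(np.arange(n_obs), np.unique(train))
    return Split(train, held, size_requested=size, scheme=scheme.scheme, repeat_id=repeat_id)


def kfold_splits(
    n_obs: int,
    k: int,
    strata: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[Split]:
    """Partition observations into k folds; each Split trains on the other k-1.

    Fold sizes differ by at most 1 and the held-out folds are an exact
    partition of all observations. With strata, folds are filled per stratum
    round-robin so class balance is approximately preserved. k may range from
    2 to n_obs (k = n_obs is leave-one-out, allowed only when explicitly
    requested with that exact value).
    """
    if rng is None:
        rng = np.random.default_rng()
    if not 2 <= k <= n_obs:
        raise ValueError(f"k must be in [2, {n_obs}]")
    fold_of = np.empty(n_obs, dtype=np.intp)
    if strata is not None:
        strata = np.asarray(strata)
        if len(strata) != n_obs:
            raise ValueError("strata length must equal n_obs")
        import warnings

        start = 0
        for lab, idx in _strata_groups(strata).items():
            if len(idx) < k:
                warnings.warn(
                    f"stratum {lab!r} has fewer observations ({len(idx)}) than folds ({k})"
                )
            perm = rng.permutation(idx)
            fold_of[perm] = (start + np.arange(len(perm))) % k
            start += len(perm)  # rotate the starting fold across strata
    else:
        perm = rng.permutation(n_obs)
        fold_of[perm] = np.arange(n_obs) % k
    splits = []
    for f in range(k):
        held = np.flatnonzero(fold_of == f)
        train = np.flatnonzero(fold_of != f)
        splits.append(
            Split(train, held, size_requested=len(train), scheme="kfold", repeat_id=f)
        )
    return splits


def export_splits(splits: list[Split], path) -> None:
    """Write splits as delimited text (repeat_id, role, 1-based index) for audit."""
    with open(path, "w") as fh:
        fh.write("repeat_id\trole\tindex\n")
        for s in splits:
            for i in s.train_idx:
                fh.write(f"{s.repeat_id}\ttrain\t{int(i) + 1}\n")
            for i in s.held_out_idx:
                fh.write(f"{s.repeat_id}\theld_out\t{int(i) + 1}\n")
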