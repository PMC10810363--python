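"""Dataset container, delimited-text I/O and synthetic data generators.

The synthetic generators make every stage of the framework testable without
external downloads. They emulate two archetypes of biomedical tabular data:

* ``simulate_classification`` -- a binary (or multiclass) diagnosis problem
  with a handful of informative features among many standard-Gaussian noise
  features; informative features carry a between-class mean shift of
  ``effect_size`` standard deviations.
* ``simulate_regression`` -- a sparse linear model y = X beta + noise with a
  known coefficient vector, mimicking, e.g., drug-response (IC50) prediction
  from expression profiles.

Both record the ground truth (informative indices, coefficients, noise scale)
so recovery can be asserted in tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "SimTruth",
    "load_dataset",
    "save_dataset",
    "simulate_classification",
    "simulate_regression",
]

#: cell values treated as missing when reading delimited text
MISSING_CODES = ("", "NA")


@dataclass
class Dataset:
    """A samples x features matrix with response and optional strata labels."""

    X: pd.DataFrame
    y: pd.Series
    task: str  # classification | regression
    strata: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("X row count must equal response length")
        if self.X.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if self.X.index.duplicated().any():
            raise ValueError("sample ids must be unique")
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.strata is not None and len(self.strata) != len(self.X):
            raise ValueError("strata length must equal number of samples")

    @property
    def n_obs(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(pd.util.hash_pandas_object(self.X, index=True).to_numpy().tobytes())
        h.update(pd.util.hash_pandas_object(self.y, index=True).to_numpy().tobytes())
        return h.hexdigest()[:16]

    def summary(self) -> dict:
        info = {
            "n_obs": self.n_obs,
            "n_features": self.n_features,
            "missing_fraction": float(self.X.isna().to_numpy().mean()),
            "task": self.task,
        }
        if self.task == "classification":
            info["class_counts"] = self.y.value_counts().sort_index().to_dict()
        return info


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated dataset, for recovery checks."""

    informative: np.ndarray  # indices into the feature axis
    coefficients: np.ndarray  # effect sizes / regression betas, aligned to informative
    noise_sd: float
    seed: int


def load_dataset(
    features_path,
    response: Union[str, "pd.Series", None] = None,
    response_path=None,
    task: str = "classification",
    strata_column: Optional[str] = None,
    sep: str = ",",
    transpose: bool = False,
) -> Dataset:
    """Load a delimited samples x features table (header row, first column = id).

    The response is either a named column of the table or a separate
    two-column file (id, value). Empty cells and ``NA`` are missing; any other
    non-numeric feature cell is an error.
    """
    df = pd.read_csv(features_path, sep=sep, index_col=0, na_values=list(MISSING_CODES), keep_default_na=False)
    if transpose:
        df = df.T
    y = None
    if isinstance(response, str):
        if response not in df.columns:
            raise ValueError(f"response column {response!r} not found")
        y = df[response]
        df = df.drop(columns=[response])
    elif response is not None:
        y = pd.Series(response, index=df.index)
    elif response_path is not None:
        rdf = pd.read_csv(response_path, sep=sep, index_col=0, na_values=list(MISSING_CODES), keep_default_na=False)
        if len(rdf) != len(df):
            raise ValueError(
                f"response length {len(rdf)} does not match {len(df)} samples"
            )
        y = rdf.iloc[:, 0]
        y.index = y.index.astype(df.index.dtype, errors="ignore")
    else:
        raise ValueError("a response column or file is required")
    strata = None
    if strata_column is not None:
        if strata_column not in df.columns:
            raise ValueError(f"strata column {strata_column!r} not found")
        strata = df[strata_column]
        df = df.drop(columns=[strata_column])
    try:
        X = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric feature cells: {exc}") from exc
    if task == "regression":
        y = pd.to_numeric(y)
    return Dataset(X=X, y=y, task=task, strata=strata)


def save_dataset(dataset: Dataset, features_path, sep: str = ",") -> None:
    """Write the dataset (features + response [+ strata] columns) as one table."""
    out = dataset.X.copy()
    out["response"] = dataset.y
    if dataset.strata is not None:
        out["strata"] = dataset.strata
    out.to_csv(features_path, sep=sep, index_label="sample_id")


def _feature_frame(M: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        M,
        columns=[f"feat_{i + 1}" for i in range(M.shape[1])],
        index=[f"s{i + 1}" for i in range(M.shape[0])],
    )


def simulate_classification(
    n_obs: int = 200,
    n_features: int = 100,
    n_informative: int = 5,
    effect_size: float = 2.0,
    class_fractions: Sequence[float] = (0.5, 0.5),
    seed: int = 0,
) -> tuple[Dataset, SimTruth]:
    """Gaussian classification data with a planted mean shift.

    Noise features are N(0,1) in every class; each informative feature is
    shifted by ``effect_size`` (in SD units) in all but the first class (for
    two classes: a shift of effect_size between the groups). Class labels are
    drawn with the given fractions; a class with zero expected members is an
    error. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    fr = np.asarray(class_fractions, dtype=float)
    if n_informative > n_features:
        raise ValueError("n_informative exceeds n_features")
    if not np.isclose(fr.sum(), 1.0):
        raise ValueError("class fractions must sum to 1")
    if (fr * n_obs < 1).any():
        raise ValueError("a class has zero expected members")
    labels = rng.choice(len(fr), size=n_obs, p=fr)
    M = rng.standard_normal((n_obs, n_features))
    informative = np.arange(n_informative)
    for j in informative:
        M[labels > 0, j] += effect_size
    X = _feature_frame(M)
    names = [f"class_{c}" for c in labels]
    y = pd.Series(names, index=X.index, name="response")
    ds = Dataset(X=X, y=y, task="classification")
    truth = SimTruth(
        informative=informative,
        coefficients=np.full(n_informative, effect_size),
        noise_sd=1.0,
        seed=seed,
    )
    return ds, truth


def simulate_regression(
    n_obs: int = 200,
    n_features: int = 50,
    n_informative: int = 3,
    coefficient_scale: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[Dataset, SimTruth]:
    """Sparse linear regression data: y = X[:, informative] . beta + N(0, sd).

    Features are independent N(0,1); the informative coefficients alternate in
    sign with magnitude ``coefficient_scale``, so sign recovery is non-trivial.
    Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    if n_informative > n_features:
        raise ValueError("n_informative exceeds n_features")
    M = rng.standard_normal((n_obs, n_features))
    informative = np.arange(n_informative)
    beta = coefficient_scale * np.array(
        [1.0 if i % 2 == 0 else -1.0 for i in range(n_informative)]
    )
    y_vals = M[:, informative] @ beta + noise_sd * rng.standard_normal(n_obs)
    X = _feature_frame(M)
    y = pd.Series(y_vals, index=X.index, name="response")
    ds = Dataset(X=X, y=y, task="regression")
    truth = SimTruth(
        informative=informative, coefficients=beta, noise_sd=noise_sd, seed=seed
    )
    return ds, truth
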