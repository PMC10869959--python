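"""Cohort data model, CSV I/O, train/test splitting and preprocessing.

The central container is :class:`FeatureTable`: an ``n x p`` matrix of
predictors (one row per treatment cycle) together with a binary outcome
vector (1 = successful pregnancy).  Categorical predictors are expected
pre-encoded as integers; missing values may be present until
:func:`impute_median` is applied.

All preprocessing statistics (medians, means, standard deviations) are
fitted on the training partition only, so that the held-out test rows
never leak into model evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = [
    "FeatureTable",
    "DataSplit",
    "SchemaError",
    "ValidationError",
    "SplitError",
    "UnimputableColumnError",
    "read_cohort",
    "write_cohort",
    "split_train_test",
    "impute_median",
    "standardize",
]

MISSING_TOKENS = ("", "NA")


class SchemaError(ValueError):
    """The input file does not have the expected columns."""


class ValidationError(ValueError):
    """A table violates the cohort data contract."""


class SplitError(ValueError):
    """A train/test partition is degenerate (e.g. a class is missing)."""


class UnimputableColumnError(ValidationError):
    """A column has no observed training value to impute from."""


@dataclass(frozen=True)
class FeatureTable:
    """Predictor matrix with named columns plus a binary outcome vector.

    Parameters
    ----------
    values
        ``(n, p)`` float array.  NaN encodes a missing entry; any other
        value must be finite.
    feature_names
        ``p`` unique column names.
    outcome
        Length-``n`` integer vector with entries in ``{0, 1}``.
    """

    values: np.ndarray
    feature_names: tuple[str, ...]
    outcome: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        outcome = np.asarray(self.outcome, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "outcome", outcome)
        if values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        n, p = values.shape
        if n < 1 or p < 1:
            raise ValidationError(f"need n >= 1 and p >= 1, got shape {values.shape}")
        if len(self.feature_names) != p:
            raise ValidationError(
                f"{len(self.feature_names)} names for {p} columns"
            )
        if len(set(self.feature_names)) != p:
            raise ValidationError("feature names must be unique")
        if outcome.shape != (n,):
            raise ValidationError("outcome length must match row count")
        bad = set(np.unique(outcome)) - {0, 1}
        if bad:
            raise ValidationError(f"outcome must be binary 0/1, found {sorted(bad)}")
        with np.errstate(invalid="ignore"):
            if np.isinf(values).any():
                raise ValidationError("values must be finite or NaN")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def subset_rows(self, rows: Sequence[int]) -> "FeatureTable":
        rows = np.asarray(rows, dtype=int)
        return FeatureTable(self.values[rows], self.feature_names, self.outcome[rows])

    def require_evaluable(self) -> None:
        """Contract for tables entering model evaluation."""
        if self.n < 2:
            raise ValidationError("need at least 2 rows for evaluation")
        if self.has_missing():
            raise ValidationError("table still has missing values; impute first")
        if len(np.unique(self.outcome)) < 2:
            raise ValidationError("both outcome classes must be present")

    def to_frame(self, outcome_column: str = "outcome") -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(self.feature_names))
        frame[outcome_column] = self.outcome
        return frame


@dataclass(frozen=True)
class DataSplit:
    """Disjoint, exhaustive train/test row indices of a table."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    test_fraction: float
    seed: int

    def __post_init__(self) -> None:
        train = np.asarray(self.train_indices, dtype=int)
        test = np.asarray(self.test_indices, dtype=int)
        object.__setattr__(self, "train_indices", train)
        object.__setattr__(self, "test_indices", test)
        if np.intersect1d(train, test).size:
            raise SplitError("train and test indices overlap")


def read_cohort(path: str | Path, outcome_column: str) -> FeatureTable:
    """Read a cohort CSV (header row, '.' decimal, ``NA``/empty = missing)."""
    frame = pd.read_csv(path, na_values=list(MISSING_TOKENS))
    if outcome_column not in frame.columns:
        raise SchemaError(
            f"outcome column {outcome_column!r} not in header: {list(frame.columns)}"
        )
    outcome_raw = frame[outcome_column]
    outcome_num = pd.to_numeric(outcome_raw, errors="coerce")
    bad = sorted(
        set(outcome_raw[~outcome_num.isin([0, 1])].astype(str))
    )
    if bad:
        raise ValidationError(
            f"outcome column {outcome_column!r} must contain only 0/1, found {bad}"
        )
    predictors = frame.drop(columns=[outcome_column])
    return FeatureTable(
        values=predictors.to_numpy(dtype=float),
        feature_names=tuple(str(c) for c in predictors.columns),
        outcome=outcome_num.to_numpy(dtype=int),
    )


def write_cohort(
    table: FeatureTable, path: str | Path, outcome_column: str = "outcome"
) -> None:
    """Write a table as CSV readable by :func:`read_cohort` (round trip)."""
    table.to_frame(outcome_column).to_csv(path, index=False, na_rep="NA")


def split_train_test(
    table: FeatureTable,
    test_fraction: float = 0.2,
    seed: int = 0,
    stratified: bool = True,
) -> DataSplit:
    """Deterministic train/test split of row indices.

    Stratification by outcome is the default: at ~30% prevalence an
    unstratified 20% split can leave too few positives in the test set.
    """
    if not 0.0 < test_fraction < 1.0:
        raise SplitError(f"test_fraction must be in (0,1), got {test_fraction}")
    if table.n < 5:
        raise SplitError("need at least 5 rows to split")
    strat = table.outcome if stratified else None
    train_idx, test_idx = train_test_split(
        np.arange(table.n),
        test_size=test_fraction,
        random_state=seed,
        shuffle=True,
        stratify=strat,
    )
    split = DataSplit(np.sort(train_idx), np.sort(test_idx), test_fraction, seed)
    if stratified:
        for part, name in ((split.train_indices, "train"), (split.test_indices, "test")):
            if len(np.unique(table.outcome[part])) < 2:
                raise SplitError(f"{name} partition lost an outcome class")
    return split


def impute_median(table: FeatureTable, split: DataSplit) -> FeatureTable:
    """Fill missing entries with per-column medians of the training rows."""
    train_values = table.values[split.train_indices]
    all_nan = np.isnan(train_values).all(axis=0)
    if all_nan.any():
        names = [table.feature_names[j] for j in np.flatnonzero(all_nan)]
        raise UnimputableColumnError(
            f"columns with no observed training value: {names}"
        )
    medians = np.nanmedian(train_values, axis=0)
    filled = np.where(np.isnan(table.values), medians[None, :], table.values)
    return FeatureTable(filled, table.feature_names, table.outcome)


def standardize(table: FeatureTable, split: DataSplit) -> FeatureTable:
    """Center/scale every column by training mean and population SD.

    Columns constant on the training rows are mapped to zero.
    """
    train_values = table.values[split.train_indices]
    mean = np.nanmean(train_values, axis=0)
    sd = np.nanstd(train_values, axis=0, ddof=0)
    scale = np.where(sd > 0, sd, 1.0)
    scaled = (table.values - mean[None, :]) / scale[None, :]
    scaled[:, sd == 0] = 0.0
    return FeatureTable(scaled, table.feature_names, table.outcome)
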