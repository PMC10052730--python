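"""Cohort table rationalization: imputation, encoding/scaling, splitting.

The cohort schema (shared with :mod:`pulmopt.datasets`):

==========  =========================================================
column      contents
==========  =========================================================
patient_id  free-form identifier
diagnosis   one of asthma / copd / infected / healthy
age         years
gender      M / F
smoking     non / ex / active
im_min ...  four numeric saliva-permittivity-style features, possibly
            missing (empty CSV cell)
==========  =========================================================

Missing numeric cells are filled with the per-diagnosis median
(class-aware imputation), falling back to the global column median when
a class has no observed value.  Categorical gaps use the within-class
mode.  Observed cells are never altered.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datasets import GENDERS, NUMERIC_FEATURES, SMOKING
from .optim.core import as_generator

__all__ = [
    "ClassMedianImputer",
    "CohortEncoder",
    "impute_missing",
    "prepare_features",
    "stratified_split",
    "read_cohort_csv",
]

_CATEGORICAL = {"gender": GENDERS, "smoking": SMOKING}


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV (empty cells become NaN)."""
    return pd.read_csv(path)


class ClassMedianImputer(TransformerMixin, BaseEstimator):
    """Impute missing cells with class-conditional medians/modes.

    Numeric columns: per-diagnosis median, global-median fallback for a
    class with no observed value.  Categorical columns: within-class
    mode, global-mode fallback.  The ``diagnosis`` label itself must be
    present in every row.  Statistics are learned in :meth:`fit` so the
    same fill values can be applied to new tables.
    """

    def __init__(self, label_column: str = "diagnosis"):
        self.label_column = label_column

    def fit(self, table: pd.DataFrame, y=None) -> "ClassMedianImputer":
        if self.label_column not in table.columns:
            raise ValueError(f"missing label column {self.label_column!r}")
        if table[self.label_column].isna().any():
            raise ValueError("diagnosis must be present for every row")

        numeric = [c for c in table.columns if c in NUMERIC_FEATURES]
        categorical = [c for c in table.columns if c in _CATEGORICAL]
        self.numeric_columns_ = numeric
        self.categorical_columns_ = categorical

        for col in numeric:
            if table[col].isna().all():
                raise ValueError(f"unimputable column {col!r}: no observed values")

        grouped = table.groupby(self.label_column, observed=True)
        self.class_medians_ = {
            col: grouped[col].median().to_dict() for col in numeric
        }
        self.global_medians_ = {col: float(table[col].median()) for col in numeric}
        self.class_modes_ = {
            col: {
                cls: (m.iloc[0] if len(m := sub[col].mode()) else None)
                for cls, sub in grouped
            }
            for col in categorical
        }
        self.global_modes_ = {
            col: (m.iloc[0] if len(m := table[col].mode()) else None)
            for col in categorical
        }
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        labels = out[self.label_column]
        for col in self.numeric_columns_:
            fills = labels.map(
                lambda cls: self.class_medians_[col].get(cls, np.nan)
            ).astype(float)
            fills = fills.fillna(self.global_medians_[col])
            out[col] = out[col].fillna(fills)
        for col in self.categorical_columns_:
            fills = labels.map(lambda cls: self.class_modes_[col].get(cls))
            fills = fills.fillna(self.global_modes_[col])
            out[col] = out[col].fillna(fills)
        return out


def impute_missing(table: pd.DataFrame) -> pd.DataFrame:
    """Fit-and-apply class-aware imputation on one table."""
    return ClassMedianImputer().fit(table).transform(table)


class CohortEncoder(TransformerMixin, BaseEstimator):
    """Encode an imputed cohort table into a numeric design matrix.

    Numeric features and age are z-scored with constants learned at fit
    time (a zero-variance column maps to all zeros); gender and smoking
    are one-hot encoded against their fixed category lists.  A category
    unseen in the fixed lists raises at transform time.

    The encoded column order is: the four numeric features, gender
    one-hot (M, F), smoking one-hot (non, ex, active), age - ten columns
    in total for the full schema.
    """

    def __init__(self, label_column: str = "diagnosis"):
        self.label_column = label_column

    def fit(self, table: pd.DataFrame, y=None) -> "CohortEncoder":
        self.scaled_columns_ = [c for c in NUMERIC_FEATURES if c in table.columns]
        if "age" in table.columns:
            self.scaled_columns_ = self.scaled_columns_ + ["age"]
        self.means_ = {}
        self.stds_ = {}
        for col in self.scaled_columns_:
            vals = table[col].astype(float)
            self.means_[col] = float(vals.mean())
            sd = float(vals.std(ddof=0))
            self.stds_[col] = sd  # 0.0 marks a constant column
        names: list[str] = [c for c in NUMERIC_FEATURES if c in table.columns]
        for col, cats in _CATEGORICAL.items():
            if col in table.columns:
                names += [f"{col}={cat}" for cat in cats]
        if "age" in table.columns:
            names.append("age")
        self.feature_names_out_ = names
        return self

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        cols: list[np.ndarray] = []
        for col in NUMERIC_FEATURES:
            if col not in table.columns:
                continue
            cols.append(self._zscore(col, table[col].to_numpy(dtype=float)))
        for col, cats in _CATEGORICAL.items():
            if col not in table.columns:
                continue
            vals = table[col].to_numpy()
            unseen = set(vals) - set(cats)
            if unseen:
                raise ValueError(f"unseen category in {col!r}: {sorted(unseen)}")
            for cat in cats:
                cols.append((vals == cat).astype(float))
        if "age" in table.columns:
            cols.append(self._zscore("age", table["age"].to_numpy(dtype=float)))
        return np.column_stack(cols)

    def _zscore(self, col: str, vals: np.ndarray) -> np.ndarray:
        sd = self.stds_[col]
        if sd == 0.0:
            return np.zeros_like(vals)
        return (vals - self.means_[col]) / sd

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.feature_names_out_, dtype=object)


def prepare_features(
    table: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, list[str], CohortEncoder]:
    """Encode an imputed table; returns (X, labels, column names, encoder).

    The fitted encoder carries the scaling constants so the same
    transform can be applied to held-out rows.
    """
    encoder = CohortEncoder().fit(table)
    X = encoder.transform(table)
    y = table["diagnosis"].to_numpy()
    return X, y, list(encoder.feature_names_out_), encoder


def stratified_split(
    labels: np.ndarray | pd.Series,
    train_frac: float = 0.7,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class deterministic split: ``floor(train_frac * n_c)`` rows of
    each class go to training, the remainder to test.

    Indices are shuffled within class with the given seed; the returned
    index arrays are sorted, disjoint, and together cover every row.
    """
    labels = np.asarray(labels)
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    rng = as_generator(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(
                f"stratification error: class {cls!r} has fewer than 2 members"
            )
        rng.shuffle(idx)
        n_train = int(np.floor(train_frac * idx.size))
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))
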