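"""Labeled feature tables, TMB dichotomization, cohort splitting, standardization.

The central container is :class:`LabeledFeatureTable`: an ``m x n`` numeric
matrix of radiomic/clinical features with a binary tumor-mutational-burden
(TMB) label per sample.  TMB-high is the positive class (label 1), obtained
either directly from a 0/1 column or by thresholding a continuous
mutations-per-megabase value at 15.5 mut/Mb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

TMB_CUTOFF = 15.5
FEATURE_CATEGORIES = ("tumor_voi", "peritumoral_voi", "clinical")


class FeatureTableError(ValueError):
    """Base error for invalid feature tables."""


class MissingValueError(FeatureTableError):
    """A sample row contains missing entries."""


class SingleClassError(FeatureTableError):
    """The label column contains only one class."""


@dataclass(frozen=True)
class LabeledFeatureTable:
    """Samples-by-features matrix with a binary TMB label.

    Parameters
    ----------
    sample_ids : sequence of str
        One identifier per row of ``X``.
    feature_names : sequence of str
        Unique column names.
    X : ndarray, shape (m, n)
        Numeric feature matrix without missing values.
    C : ndarray, shape (m,)
        Binary labels; 1 = TMB-high, 0 = TMB-low.  Both classes present.
    feature_category : sequence of str, optional
        Per-feature tag in ``FEATURE_CATEGORIES``; defaults to ``tumor_voi``.
    """

    sample_ids: tuple
    feature_names: tuple
    X: np.ndarray
    C: np.ndarray
    feature_category: tuple = field(default=())

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        C = np.asarray(self.C, dtype=int)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_names", tuple(str(f) for f in self.feature_names))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "C", C)
        if X.ndim != 2 or X.shape != (len(self.sample_ids), len(self.feature_names)):
            raise FeatureTableError(
                f"X shape {X.shape} inconsistent with {len(self.sample_ids)} samples "
                f"and {len(self.feature_names)} features"
            )
        if not np.all(np.isfinite(X)):
            bad = [self.sample_ids[i] for i in np.unique(np.where(~np.isfinite(X))[0])]
            raise MissingValueError(f"missing/non-finite values in samples: {bad}")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise FeatureTableError("feature names are not unique")
        if not set(np.unique(C)) <= {0, 1}:
            raise FeatureTableError("labels must be binary (0 = TMB-low, 1 = TMB-high)")
        if len(set(np.unique(C))) < 2:
            raise SingleClassError("label column contains a single class")
        cats = self.feature_category or ("tumor_voi",) * len(self.feature_names)
        cats = tuple(cats)
        if len(cats) != len(self.feature_names):
            raise FeatureTableError("feature_category length mismatch")
        unknown = set(cats) - set(FEATURE_CATEGORIES)
        if unknown:
            raise FeatureTableError(f"unknown feature categories: {sorted(unknown)}")
        object.__setattr__(self, "feature_category", cats)

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]

    def feature_index(self, name: str) -> int:
        return self.feature_names.index(name)

    def to_dataframe(self, label_column: str = "TMB_label") -> pd.DataFrame:
        df = pd.DataFrame(self.X, index=list(self.sample_ids), columns=list(self.feature_names))
        df.index.name = "sample_id"
        df[label_column] = self.C
        return df


def label_from_tmb(mut_per_mb: Sequence[float], cutoff: float = TMB_CUTOFF) -> np.ndarray:
    """Dichotomize mutations-per-megabase at *cutoff* (default 15.5 mut/Mb).

    Values at or above the cutoff are TMB-high (1); the boundary is inclusive.
    """
    values = np.asarray(mut_per_mb, dtype=float)
    if np.any(values < 0):
        raise ValueError("mutation burden cannot be negative")
    return (values >= cutoff).astype(int)


def load_feature_table(
    path,
    label_column: str,
    category_map: Mapping[str, str] | None = None,
    tmb_cutoff: float = TMB_CUTOFF,
) -> LabeledFeatureTable:
    """Read a CSV feature table (first column sample id, first row header).

    The label column may be binary (0/1) or a continuous mut/Mb value, in
    which case it is thresholded at ``tmb_cutoff``.  Rows with missing
    entries and non-numeric cells raise named errors; constant features are
    reported via a warning.
    """
    df = pd.read_csv(path, index_col=0)
    if label_column not in df.columns:
        raise FeatureTableError(f"label column {label_column!r} not found in {path}")
    label_raw = pd.to_numeric(df[label_column], errors="coerce")
    feats = df.drop(columns=[label_column])
    feats_num = feats.apply(pd.to_numeric, errors="coerce")
    bad_cells = feats_num.isna() & ~feats.isna()
    if bad_cells.any().any():
        rows = feats.index[bad_cells.any(axis=1)].tolist()
        raise FeatureTableError(f"non-numeric feature cells in samples: {rows}")
    missing = feats_num.isna().any(axis=1) | label_raw.isna()
    if missing.any():
        raise MissingValueError(
            f"rows with missing values rejected: {feats.index[missing].tolist()}"
        )
    labels = label_raw.to_numpy(dtype=float)
    if set(np.unique(labels)) <= {0.0, 1.0}:
        C = labels.astype(int)
    else:
        C = label_from_tmb(labels, cutoff=tmb_cutoff)
    if len(np.unique(C)) < 2:
        raise SingleClassError(f"label column {label_column!r} yields a single class")
    names = [str(c) for c in feats_num.columns]
    cats = None
    if category_map is not None:
        cats = tuple(category_map.get(nm, "tumor_voi") for nm in names)
    X = feats_num.to_numpy(dtype=float)
    const = [names[j] for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0]
    if const:
        warnings.warn(f"constant (zero-variance) features: {const}", UserWarning)
    return LabeledFeatureTable(
        sample_ids=tuple(str(i) for i in feats.index),
        feature_names=tuple(names),
        X=X,
        C=C,
        feature_category=cats or (),
    )


def save_feature_table(table: LabeledFeatureTable, path, label_column: str = "TMB_label") -> None:
    table.to_dataframe(label_column).to_csv(path)


def load_category_map(path) -> dict:
    """Two-column CSV (feature_name, category) -> per-feature category dict."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FeatureTableError("category map needs columns (feature_name, category)")
    name_col, cat_col = df.columns[:2]
    mapping = dict(zip(df[name_col].astype(str), df[cat_col].astype(str)))
    unknown = set(mapping.values()) - set(FEATURE_CATEGORIES)
    if unknown:
        raise FeatureTableError(f"unknown feature categories: {sorted(unknown)}")
    return mapping


@dataclass(frozen=True)
class CohortSplit:
    """Disjoint train/test/validation index sets over a cohort."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    validation_idx: np.ndarray
    ratios: tuple
    seed: int

    def __post_init__(self):
        for name in ("train_idx", "test_idx", "validation_idx"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=int))
        all_idx = np.concatenate([self.train_idx, self.test_idx, self.validation_idx])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split index sets are not disjoint")

    @property
    def splits(self) -> dict:
        return {
            "train": self.train_idx,
            "test": self.test_idx,
            "validation": self.validation_idx,
        }

    def to_manifest(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        rows = []
        for name, idx in self.splits.items():
            for i in idx:
                rows.append({"sample_id": sample_ids[i], "split": name})
        return pd.DataFrame(rows).sort_values("sample_id").reset_index(drop=True)


def _apportion(quotas: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of *total* seats to real-valued quotas."""
    base = np.floor(quotas).astype(int)
    rem = quotas - base
    short = total - base.sum()
    order = np.lexsort((np.arange(len(quotas)), -rem))
    for i in order[:short]:
        base[i] += 1
    return base


def split_cohort(
    table: LabeledFeatureTable,
    ratios: tuple = (0.70, 0.20, 0.10),
    seed: int = 0,
    stratify: bool = True,
) -> CohortSplit:
    """Randomly partition the cohort into train/test/validation.

    Split sizes are ``round(m * ratio)`` for test and validation with the
    remainder absorbed by train.  By default the split is stratified so each
    subset keeps the global class balance and contains both classes.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise ValueError("ratios must be three positive fractions")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    m = table.m
    n_test = int(round(m * ratios[1]))
    n_val = int(round(m * ratios[2]))
    n_train = m - n_test - n_val
    if min(n_train, n_test, n_val) < 1:
        raise ValueError(f"cohort of {m} samples too small for ratios {ratios}")
    rng = np.random.default_rng(seed)

    if not stratify:
        perm = rng.permutation(m)
        return CohortSplit(perm[:n_train], perm[n_train : n_train + n_test],
                           perm[n_train + n_test :], ratios, seed)

    classes = [np.flatnonzero(table.C == c) for c in (0, 1)]
    class_sizes = np.array([len(c) for c in classes])
    if class_sizes.min() < 3:
        raise ValueError("minority class too small to stratify a three-way split")
    te_counts = _apportion(class_sizes * ratios[1], n_test)
    va_counts = _apportion(class_sizes * ratios[2], n_val)
    # every split must be scoreable: force at least one sample per class
    # (impossible for single-sample splits, which keep their apportionment)
    for counts in (te_counts, va_counts):
        if counts.sum() < 2:
            continue
        for c in range(2):
            if counts[c] == 0:
                counts[c] = 1
                counts[1 - c] -= 1
    tr_counts = class_sizes - te_counts - va_counts
    if tr_counts.min() < 1:
        raise ValueError("minority class too small to stratify a three-way split")

    train, test, val = [], [], []
    for c in range(2):
        idx = rng.permutation(classes[c])
        test.append(idx[: te_counts[c]])
        val.append(idx[te_counts[c] : te_counts[c] + va_counts[c]])
        train.append(idx[te_counts[c] + va_counts[c] :])
    return CohortSplit(
        np.sort(np.concatenate(train)),
        np.sort(np.concatenate(test)),
        np.sort(np.concatenate(val)),
        ratios,
        seed,
    )


@dataclass(frozen=True)
class StandardizationParams:
    feature_names: tuple
    mean: np.ndarray
    scale: np.ndarray

    def to_yaml(self, path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "mean": [float(v) for v in self.mean],
            "scale": [float(v) for v in self.scale],
        }
        Path(path).write_text(yaml.safe_dump(payload))

    @classmethod
    def from_yaml(cls, path) -> "StandardizationParams":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            tuple(payload["feature_names"]),
            np.asarray(payload["mean"], dtype=float),
            np.asarray(payload["scale"], dtype=float),
        )


def standardize(
    table: LabeledFeatureTable, fit_idx: Sequence[int] | None = None
) -> tuple[LabeledFeatureTable, StandardizationParams]:
    """Center/scale each feature by mean and population SD computed on *fit_idx*.

    All rows are transformed with the fit-subset parameters, so held-out
    samples never leak into the scaling.  Zero-variance features are centered
    and left unscaled (scale 1).
    """
    if fit_idx is None:
        fit_idx = np.arange(table.m)
    fit_idx = np.asarray(fit_idx, dtype=int)
    if fit_idx.size == 0:
        raise ValueError("fit_idx must be nonempty")
    sub = table.X[fit_idx]
    mean = sub.mean(axis=0)
    scale = sub.std(axis=0, ddof=0)
    scale = np.where(scale == 0, 1.0, scale)
    params = StandardizationParams(table.feature_names, mean, scale)
    return apply_standardization(table, params), params


def apply_standardization(
    table: LabeledFeatureTable, params: StandardizationParams
) -> LabeledFeatureTable:
    if tuple(params.feature_names) != table.feature_names:
        raise FeatureTableError("standardization parameters do not match table features")
    Xs = (table.X - params.mean) / params.scale
    return replace(table, X=Xs)
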