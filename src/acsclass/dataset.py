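"""Labeled mixed-type datasets: delimited I/O and min-max normalization.

A :class:`Dataset` couples an ``n x p`` numeric value matrix with integer
class labels (``1..C``) and the :class:`~acsclass.schema.FeatureSchema`
describing each column. Continuous (ratio) features are rescaled to a
target interval — ``[-1, 1]`` by default — by the affine min-max map

    x' = lo + (hi - lo) * (x - min) / (max - min)

with ``min``/``max`` taken from a *fit* sample (normally the training
split, to avoid leakage into test data). Values outside the fit range map
outside the target interval; no clipping is applied, so the transform is
strictly monotone. A constant (degenerate) feature maps to the interval
midpoint and is flagged.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import FeatureSchema

LABEL_COLUMN = "class"


class DataError(ValueError):
    """Raised for rows violating the schema contract."""


@dataclass(frozen=True)
class Dataset:
    """Coded feature matrix plus class labels under a schema contract."""

    values: np.ndarray
    labels: np.ndarray
    schema: FeatureSchema

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        if values.ndim != 2:
            raise DataError("values must be a 2-D matrix")
        if values.shape[0] == 0:
            raise DataError("dataset is empty")
        if values.shape[1] != len(self.schema):
            raise DataError(
                f"{values.shape[1]} columns for {len(self.schema)} schema features"
            )
        if labels.shape != (values.shape[0],):
            raise DataError("labels must be one per row")
        if labels.min() < 1 or labels.max() > self.schema.n_classes:
            raise DataError(
                f"labels must lie in 1..{self.schema.n_classes}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> np.ndarray:
        """Per-class row counts, indexed by class-1."""
        return np.bincount(self.labels, minlength=self.schema.n_classes + 1)[1:]

    def select_rows(self, idx: Sequence[int]) -> "Dataset":
        idx = np.asarray(idx, dtype=int)
        return Dataset(self.values[idx], self.labels[idx], self.schema)

    def select_features(self, labels: Sequence[int]) -> "Dataset":
        """Dataset restricted to the given feature labels (schema order)."""
        sub = self.schema.subset(labels)
        cols = [self.schema.column_of(f.label) for f in sub]
        return Dataset(self.values[:, cols], self.labels, sub)

    def validate_codes(self) -> None:
        """Check every categorical value against its feature's code set."""
        for j, spec in enumerate(self.schema):
            if not spec.is_categorical:
                continue
            col = self.values[:, j]
            allowed = np.array(spec.codes, dtype=float)
            bad = ~np.isin(col, allowed)
            if bad.any():
                row = int(np.nonzero(bad)[0][0])
                raise DataError(
                    f"row {row}: value {col[row]:g} of feature "
                    f"{spec.label} ({spec.name!r}) not in codes {spec.codes}"
                )


def read_dataset(table_text: str, schema: FeatureSchema, sep: str | None = None) -> Dataset:
    """Parse a delimited table (header row + ``class`` label column).

    Column headers must match the schema feature names; the label column is
    named ``class``. Comma and tab delimiters are auto-detected unless
    ``sep`` is given. Missing cells, out-of-code categorical values and
    out-of-range labels raise :class:`DataError` naming the offending row.
    """
    if sep is None:
        first = table_text.splitlines()[0] if table_text else ""
        sep = "\t" if "\t" in first else ","
    df = pd.read_csv(io.StringIO(table_text), sep=sep)
    if LABEL_COLUMN not in df.columns:
        raise DataError(f"missing label column {LABEL_COLUMN!r}")
    expected = list(schema.names)
    got = [c for c in df.columns if c != LABEL_COLUMN]
    if got != expected:
        raise DataError(
            f"header mismatch: expected {expected[:3]}... got {got[:3]}..."
        )
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise DataError(f"missing values in rows {rows}")
    values = df[expected].to_numpy(dtype=float)
    labels_raw = df[LABEL_COLUMN].to_numpy()
    labels = labels_raw.astype(int)
    if not np.allclose(labels_raw.astype(float), labels):
        raise DataError("non-integer class labels")
    bad = (labels < 1) | (labels > schema.n_classes)
    if bad.any():
        row = int(np.nonzero(bad)[0][0])
        raise DataError(
            f"row {row}: label {labels[row]} outside 1..{schema.n_classes}"
        )
    ds = Dataset(values, labels, schema)
    ds.validate_codes()
    return ds


def write_dataset(data: Dataset, sep: str = ",") -> str:
    """Serialize a dataset to delimited text (inverse of :func:`read_dataset`)."""
    df = pd.DataFrame(data.values, columns=list(data.schema.names))
    # keep integer-valued columns as integers for clean round-trips
    for c in df.columns:
        col = df[c]
        if np.allclose(col, np.round(col)):
            df[c] = col.astype(int)
    df[LABEL_COLUMN] = data.labels
    return df.to_csv(index=False, sep=sep)


@dataclass(frozen=True)
class NormStats:
    """Per-feature min/max fitted for min-max normalization.

    ``degenerate`` flags features whose fit sample was constant
    (``min == max``); these are mapped to the target-interval midpoint.
    """

    minima: Mapping[int, float]
    maxima: Mapping[int, float]
    degenerate: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        for lab, lo in self.minima.items():
            if self.maxima[lab] < lo:
                raise DataError(f"feature {lab}: max < min in normalizer stats")

    @property
    def feature_labels(self) -> frozenset[int]:
        return frozenset(self.minima)


def fit_normalizer(data: Dataset, feature_subset: Iterable[int] | None = None) -> NormStats:
    """Observe per-feature extrema on ``data`` for later normalization.

    ``feature_subset`` defaults to all ratio features present in the
    schema; categorical labels in the subset are rejected. A constant
    feature is recorded with a degenerate flag and a warning.
    """
    if feature_subset is None:
        feature_subset = data.schema.ratio_labels
    minima: dict[int, float] = {}
    maxima: dict[int, float] = {}
    degenerate: set[int] = set()
    for lab in feature_subset:
        spec = data.schema.feature(lab)
        if not spec.is_ratio:
            raise DataError(f"feature {lab} ({spec.name!r}) is not a ratio feature")
        col = data.values[:, data.schema.column_of(lab)]
        lo, hi = float(col.min()), float(col.max())
        minima[lab] = lo
        maxima[lab] = hi
        if lo == hi:
            degenerate.add(lab)
            warnings.warn(
                f"feature {lab} ({spec.name!r}) is constant in the fit sample; "
                "it will normalize to the interval midpoint",
                stacklevel=2,
            )
    return NormStats(minima, maxima, frozenset(degenerate))


def apply_normalizer(data: Dataset, stats: NormStats) -> Dataset:
    """Min-max rescale every covered ratio feature into its target range.

    Fit-sample extrema map to the interval endpoints; out-of-range values
    extend affinely beyond them (no clipping). Degenerate features map to
    the interval midpoint. Categorical features pass through unchanged.
    """
    values = data.values.copy()
    for lab in data.schema.ratio_labels:
        if lab not in stats.feature_labels:
            raise DataError(f"normalizer stats missing ratio feature {lab}")
        spec = data.schema.feature(lab)
        lo_t, hi_t = spec.target_range
        j = data.schema.column_of(lab)
        if lab in stats.degenerate:
            values[:, j] = 0.5 * (lo_t + hi_t)
            continue
        mn, mx = stats.minima[lab], stats.maxima[lab]
        values[:, j] = lo_t + (hi_t - lo_t) * (values[:, j] - mn) / (mx - mn)
    return Dataset(values, data.labels, data.schema)


def normalize(train: Dataset, *others: Dataset, scope: str = "split") -> tuple[Dataset, ...]:
    """Fit-and-apply helper for the two supported normalization scopes.

    ``scope="split"`` fits extrema on ``train`` only (default; avoids
    leaking test-set range information); ``scope="global"`` fits on the
    concatenation of all parts, mirroring a single whole-dataset rescale.
    Returns the normalized datasets in input order.
    """
    if scope == "split":
        fit_on = train
    elif scope == "global":
        if others:
            allv = np.vstack([train.values] + [d.values for d in others])
            alll = np.concatenate([train.labels] + [d.labels for d in others])
            fit_on = Dataset(allv, alll, train.schema)
        else:
            fit_on = train
    else:
        raise ValueError(f"unknown normalization scope {scope!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stats = fit_normalizer(fit_on)
    return tuple(apply_normalizer(d, stats) for d in (train, *others))
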