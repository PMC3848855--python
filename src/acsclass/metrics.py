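"""Confusion-matrix performance metrics for multi-class classifiers.

Beyond overall accuracy, two conditional-probability views of a confusion
matrix ``CM`` (rows = actual class, columns = predicted class) are
provided:

* **APM** (accuracy probability matrix): each row of the CM divided by its
  row sum, so entry ``(i, j)`` estimates ``p(predicted j | actual i)``.
  The diagonal is the per-class sensitivity.
* **CPM** (correctness probability matrix): the Bayes inversion of the APM
  under class priors ``p(c_i)``,

      CPM[i, j] = APM[i, j] p(c_i) / sum_k APM[k, j] p(c_k),

  so entry ``(i, j)`` estimates ``p(actual i | predicted j)`` — the
  probability that a sample *called* class ``j`` truly belongs to class
  ``i``. Under the empirical priors of the same confusion matrix this
  reduces algebraically to column-normalizing the CM.

Zero-support rows/columns yield zero rows/columns plus a machine-readable
flag rather than NaN. Aggregation across repeated evaluation runs reports
the element-wise mean and sample standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C count matrix; rows index the actual class, columns the predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise MetricError("confusion matrix must be square")
        if (counts < 0).any():
            raise MetricError("confusion matrix entries must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class ProbMatrix:
    """Row- (APM) or column- (CPM) stochastic probability matrix.

    ``unsupported`` lists row (APM) or column (CPM) indices with zero
    support, whose entries are zero by convention.
    """

    probs: np.ndarray
    orientation: str  # "APM" | "CPM"
    unsupported: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if self.orientation not in ("APM", "CPM"):
            raise MetricError(f"unknown orientation {self.orientation!r}")

    def diagonal(self) -> np.ndarray:
        return np.diag(self.probs)


@dataclass(frozen=True)
class ClassPriors:
    """Length-C prior class probability vector."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise MetricError("class priors must sum to 1")
        if (probs < 0).any():
            raise MetricError("class priors must be non-negative")


def build_cm(actual: Sequence[int], predicted: Sequence[int], n_classes: int) -> ConfusionMatrix:
    """Tabulate actual-vs-predicted counts; labels are 1-based."""
    actual = np.asarray(actual, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if actual.shape != predicted.shape:
        raise MetricError("actual and predicted label vectors differ in length")
    if actual.size and (
        actual.min() < 1 or actual.max() > n_classes
        or predicted.min() < 1 or predicted.max() > n_classes
    ):
        raise MetricError(f"labels must lie in 1..{n_classes}")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (actual - 1, predicted - 1), 1)
    return ConfusionMatrix(counts)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Trace over grand total: the fraction of correctly labeled samples."""
    total = cm.total
    if total == 0:
        raise MetricError("empty confusion matrix has no accuracy")
    return float(np.trace(cm.counts)) / total


def compute_apm(cm: ConfusionMatrix) -> ProbMatrix:
    """Row-condition the CM: entry (i, j) = p(predicted j | actual i)."""
    counts = cm.counts.astype(float)
    rows = counts.sum(axis=1)
    supported = rows > 0
    probs = np.zeros_like(counts)
    probs[supported] = counts[supported] / rows[supported, None]
    flagged = tuple(int(i) for i in np.nonzero(~supported)[0])
    return ProbMatrix(probs, "APM", flagged)


def compute_cpm(apm: ProbMatrix, priors: ClassPriors) -> ProbMatrix:
    """Bayes-invert an APM with class priors: entry (i, j) = p(actual i | predicted j)."""
    if apm.orientation != "APM":
        raise MetricError("compute_cpm expects an APM")
    joint = apm.probs * priors.probs[:, None]
    cols = joint.sum(axis=0)
    supported = cols > 0
    probs = np.zeros_like(joint)
    probs[:, supported] = joint[:, supported] / cols[supported]
    flagged = tuple(int(j) for j in np.nonzero(~supported)[0])
    return ProbMatrix(probs, "CPM", flagged)


def empirical_priors(counts: Sequence[int]) -> ClassPriors:
    """Class priors as observed relative frequencies."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise MetricError("cannot form priors from zero total count")
    return ClassPriors(counts / total)


@dataclass(frozen=True)
class AggregateResult:
    """Element-wise mean and sample std of a list of same-shape matrices."""

    mean: np.ndarray
    std: np.ndarray
    n_runs: int
    single_run: bool = False


def aggregate_runs(matrices: Sequence[np.ndarray]) -> AggregateResult:
    """Aggregate repeated-run matrices as mean ± sample standard deviation.

    Uses the n-1 denominator; a single run reports zero std with the
    ``single_run`` flag set.
    """
    if len(matrices) == 0:
        raise MetricError("no matrices to aggregate")
    arrs = [np.asarray(m, dtype=float) for m in matrices]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise MetricError("matrices differ in shape")
    stack = np.stack(arrs)
    mean = stack.mean(axis=0)
    if len(arrs) == 1:
        return AggregateResult(mean, np.zeros(shape), 1, single_run=True)
    std = stack.std(axis=0, ddof=1)
    return AggregateResult(mean, std, len(arrs))
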