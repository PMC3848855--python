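"""ID3 decision tree and its bootstrap-aggregated (bagging) ensemble.

The tree is grown recursively, choosing at each node the split with the
largest information gain (entropy in bits). Categorical features split
multiway over their observed codes; continuous features split binarily at
the best midpoint between sorted distinct values. Leaves predict the local
majority class; an unseen categorical code at prediction time falls
through to the node's majority class. The bagging ensemble trains ``B``
trees on seeded bootstrap resamples (size n, with replacement) and takes a
plurality vote, with ties resolved toward the lower class label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..dataset import Dataset
from .base import BaseClassifier, ClassifierError


def entropy_bits(labels: np.ndarray) -> float:
    """Shannon entropy of a label vector, in bits."""
    if labels.size == 0:
        return 0.0
    counts = np.bincount(labels)
    p = counts[counts > 0] / labels.size
    return float(-(p * np.log2(p)).sum())


@dataclass
class _Node:
    majority: int
    column: int | None = None  # None -> leaf
    categorical: bool = False
    branches: dict | None = None  # code -> _Node (categorical)
    threshold: float | None = None
    left: "_Node | None" = None  # value <= threshold
    right: "_Node | None" = None


def _majority(labels: np.ndarray) -> int:
    counts = np.bincount(labels)
    return int(np.argmax(counts))  # lowest label wins ties


def _entropy_rows(counts: np.ndarray) -> np.ndarray:
    """Entropy in bits of each row of a count matrix."""
    totals = counts.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
        h = np.where(p > 0, -p * np.log2(np.maximum(p, 1e-300)), 0.0)
    return h.sum(axis=-1)


def best_split(values: np.ndarray, labels: np.ndarray, categorical: np.ndarray):
    """Exhaustive best split over all columns; returns (gain, col, threshold).

    ``threshold`` is None for a categorical (multiway) split. Ties prefer
    the lower column index (and the lower threshold within a column),
    matching the greedy growth order.
    """
    n = labels.size
    C = int(labels.max()) + 1
    base = entropy_bits(labels)
    onehot = np.eye(C)[labels]
    best = (0.0, None, None)
    for j in range(values.shape[1]):
        col = values[:, j]
        if categorical[j]:
            codes, inv = np.unique(col, return_inverse=True)
            if codes.size < 2:
                continue
            counts = np.zeros((codes.size, C))
            np.add.at(counts, inv, onehot)
            weights = counts.sum(axis=1) / n
            gain = base - float((weights * _entropy_rows(counts)).sum())
            if gain > best[0] + 1e-12:
                best = (gain, j, None)
        else:
            order = np.argsort(col, kind="stable")
            sv = col[order]
            cum = np.cumsum(onehot[order], axis=0)  # prefix class counts
            cuts = np.nonzero(np.diff(sv) > 0)[0]  # split after position i
            if cuts.size == 0:
                continue
            left = cum[cuts]
            right = cum[-1] - left
            nl = left.sum(axis=1)
            cond = nl / n * _entropy_rows(left) + (n - nl) / n * _entropy_rows(right)
            gains = base - cond
            gi = int(np.argmax(gains))  # first max -> lowest threshold
            if gains[gi] > best[0] + 1e-12:
                thr = float((sv[cuts[gi]] + sv[cuts[gi] + 1]) / 2.0)
                best = (float(gains[gi]), j, thr)
    return best


class ID3Classifier(BaseClassifier):
    kind = "id3"

    def __init__(self, min_samples_split: int = 2, max_depth: int | None = None):
        self.min_samples_split = min_samples_split
        self.max_depth = max_depth

    def fit(self, train: Dataset, validation: Dataset | None = None) -> "ID3Classifier":
        self._categorical = np.array([f.is_categorical for f in train.schema])
        self._root = self._grow(train.values, train.labels, depth=0)
        self._remember_training(train)
        return self

    def _grow(self, values: np.ndarray, labels: np.ndarray, depth: int) -> _Node:
        node = _Node(majority=_majority(labels))
        if (
            np.unique(labels).size == 1
            or labels.size < self.min_samples_split
            or (self.max_depth is not None and depth >= self.max_depth)
        ):
            return node
        gain, col, thr = best_split(values, labels, self._categorical)
        if col is None or gain <= 0:
            return node
        node.column = col
        if thr is None:
            node.categorical = True
            node.branches = {}
            for code in np.unique(values[:, col]):
                mask = values[:, col] == code
                node.branches[float(code)] = self._grow(values[mask], labels[mask], depth + 1)
        else:
            node.threshold = thr
            mask = values[:, col] <= thr
            node.left = self._grow(values[mask], labels[mask], depth + 1)
            node.right = self._grow(values[~mask], labels[~mask], depth + 1)
        return node

    def _classify_one(self, x: np.ndarray) -> int:
        node = self._root
        while node.column is not None:
            if node.categorical:
                child = node.branches.get(float(x[node.column]))
                if child is None:  # unseen code: fall through to majority
                    return node.majority
                node = child
            else:
                node = node.left if x[node.column] <= node.threshold else node.right
        return node.majority

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._as_matrix(X)
        return np.array([self._classify_one(row) for row in X], dtype=int)


class BaggingID3Classifier(BaseClassifier):
    """Plurality vote over B bootstrap-trained ID3 trees."""

    kind = "bagging_id3"

    def __init__(
        self,
        n_estimators: int = 50,
        seed: int = 0,
        min_samples_split: int = 2,
        max_depth: int | None = None,
        resample: bool = True,
    ):
        if n_estimators < 1:
            raise ClassifierError("n_estimators must be positive")
        self.n_estimators = n_estimators
        self.seed = seed
        self.min_samples_split = min_samples_split
        self.max_depth = max_depth
        self.resample = resample  # test hook: identity resample when False

    def fit(self, train: Dataset, validation: Dataset | None = None) -> "BaggingID3Classifier":
        rng = np.random.default_rng(self.seed)
        self._trees = []
        for _ in range(self.n_estimators):
            if self.resample:
                idx = rng.integers(0, train.n, size=train.n)
                boot = train.select_rows(idx)
            else:
                boot = train
            tree = ID3Classifier(self.min_samples_split, self.max_depth)
            self._trees.append(tree.fit(boot))
        self._remember_training(train)
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._as_matrix(X)
        votes = np.stack([t.predict(X) for t in self._trees])  # (B, n)
        out = np.empty(X.shape[0], dtype=int)
        for i in range(X.shape[0]):
            counts = np.bincount(votes[:, i], minlength=self._n_classes + 1)
            out[i] = int(np.argmax(counts[1:]) + 1)  # ties -> lower label
        return out
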