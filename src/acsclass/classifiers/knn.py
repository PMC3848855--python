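"""k-nearest-neighbor classifier with deterministic tie-breaking.

Distances are Euclidean over the coded/normalized feature vectors. The
query is assigned the most abundant class among its k nearest training
samples. All ties are resolved deterministically: among classes with equal
vote counts the one with the smaller mean neighbor distance wins, then the
lower class index; equal distances at the k-th neighbor are resolved by
training-row order.
"""

from __future__ import annotations

import numpy as np

from ..dataset import Dataset
from .base import BaseClassifier, ClassifierError


def majority_vote(neigh_labels: np.ndarray, neigh_dists: np.ndarray, n_classes: int) -> np.ndarray:
    """Vectorized plurality vote over neighbor labels (rows = queries).

    Tie-break: smallest mean neighbor distance among tied classes, then
    lowest class index.
    """
    n, k = neigh_labels.shape
    onehot = np.zeros((n, k, n_classes))
    rows = np.arange(n)[:, None]
    onehot[rows, np.arange(k)[None, :], neigh_labels - 1] = 1.0
    counts = onehot.sum(axis=1)
    dist_sums = (onehot * neigh_dists[:, :, None]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_d = np.where(counts > 0, dist_sums / np.maximum(counts, 1), np.inf)
    tied = counts == counts.max(axis=1, keepdims=True)
    # argmin over mean distance restricted to top-count classes; argmin's
    # first-hit rule supplies the lowest-class-index fallback
    return np.argmin(np.where(tied, mean_d, np.inf), axis=1) + 1


def sq_distances(queries: np.ndarray, train: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances, (n_query, n_train)."""
    diff = queries[:, None, :] - train[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


class KNNClassifier(BaseClassifier):
    """Lazy learner storing the training set and neighbor count ``k``."""

    kind = "knn"

    def __init__(self, k: int = 7):
        if k < 1 or k % 2 == 0:
            raise ClassifierError("k must be an odd positive integer")
        self.k = k

    def fit(self, train: Dataset, validation: Dataset | None = None) -> "KNNClassifier":
        if self.k > train.n:
            raise ClassifierError(f"k={self.k} exceeds training size {train.n}")
        self._X = train.values.copy()
        self._y = train.labels.copy()
        self._remember_training(train)
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._as_matrix(X)
        d2 = sq_distances(X, self._X)
        # stable sort: equal distances keep training-row order
        order = np.argsort(d2, axis=1, kind="stable")[:, : self.k]
        neigh_d = np.sqrt(np.take_along_axis(d2, order, axis=1))
        neigh_y = self._y[order]
        return majority_vote(neigh_y, neigh_d, self._n_classes)
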