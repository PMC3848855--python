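"""Radial-basis-function network trained by the classic two-step hybrid.

Step 1 (unsupervised): place ``m`` Gaussian centers by seeded k-means on
the training features; each center's spread is the mean distance to its
nearest other center (with a single center, the overall feature spread).
Step 2 (supervised): solve ridge-regularized least squares from the
Gaussian activations (plus bias) to one-hot class targets. Prediction is
the argmax over the linear outputs.
"""

from __future__ import annotations

import numpy as np

from ..dataset import Dataset
from .base import BaseClassifier, ClassifierError
from .knn import sq_distances


def kmeans(X: np.ndarray, m: int, rng: np.random.Generator, max_iter: int = 100) -> np.ndarray:
    """Plain seeded Lloyd's algorithm; returns the (m, p) center matrix."""
    distinct = np.unique(X, axis=0)
    if m > distinct.shape[0]:
        raise ClassifierError(
            f"{m} centers requested but only {distinct.shape[0]} distinct points"
        )
    centers = distinct[rng.choice(distinct.shape[0], size=m, replace=False)]
    for _ in range(max_iter):
        d2 = sq_distances(X, centers)
        assign = np.argmin(d2, axis=1)
        new = centers.copy()
        for c in range(m):
            mask = assign == c
            if mask.any():
                new[c] = X[mask].mean(axis=0)
            else:  # re-seed an empty cluster at the worst-covered point
                new[c] = X[np.argmax(d2.min(axis=1))]
        if np.allclose(new, centers):
            break
        centers = new
    return centers


class RBFClassifier(BaseClassifier):
    kind = "rbf"

    def __init__(self, n_centers: int = 7, ridge: float = 1e-8, seed: int = 0):
        if n_centers < 1:
            raise ClassifierError("center count must be >= 1")
        if ridge < 0:
            raise ClassifierError("ridge constant must be >= 0")
        self.n_centers = n_centers
        self.ridge = ridge
        self.seed = seed

    def fit(self, train: Dataset, validation: Dataset | None = None) -> "RBFClassifier":
        rng = np.random.default_rng(self.seed)
        X = train.values
        self._centers = kmeans(X, self.n_centers, rng)
        if self.n_centers == 1:
            spread = float(np.sqrt(X.var(axis=0).sum()))
            self._spreads = np.array([max(spread, 1e-6)])
        else:
            dc = np.sqrt(sq_distances(self._centers, self._centers))
            np.fill_diagonal(dc, np.inf)
            nearest = dc.min(axis=1)
            self._spreads = np.maximum(np.full(self.n_centers, nearest.mean()), 1e-6)
        Phi = self._design(X)
        C = train.schema.n_classes
        T = np.eye(C)[train.labels - 1]
        A = Phi.T @ Phi + self.ridge * np.eye(Phi.shape[1])
        self._weights = np.linalg.solve(A, Phi.T @ T) if self.ridge > 0 else np.linalg.lstsq(Phi, T, rcond=None)[0]
        self._remember_training(train)
        return self

    def _design(self, X: np.ndarray) -> np.ndarray:
        d2 = sq_distances(X, self._centers)
        act = np.exp(-d2 / (2.0 * self._spreads[None, :] ** 2))
        return np.column_stack([act, np.ones(X.shape[0])])

    def class_scores(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._as_matrix(X)
        return self._design(X) @ self._weights

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.class_scores(X), axis=1) + 1
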