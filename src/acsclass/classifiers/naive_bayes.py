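"""Naive Bayes for mixed categorical/continuous clinical features.

Class priors are empirical frequencies. Categorical conditionals are
Laplace-smoothed code frequencies, ``(count + alpha) / (n_c + alpha *
n_codes)``; ratio conditionals are per-class Gaussians with a variance
floor so that zero-within-class-variance features stay finite. The
posterior is maximized in log space.
"""

from __future__ import annotations

import numpy as np

from ..dataset import Dataset
from .base import BaseClassifier, ClassifierError


class NaiveBayesClassifier(BaseClassifier):
    kind = "naive_bayes"

    def __init__(self, alpha: float = 1.0, var_floor: float = 1e-9):
        if alpha < 0:
            raise ClassifierError("smoothing alpha must be >= 0")
        if var_floor <= 0:
            raise ClassifierError("variance floor must be > 0")
        self.alpha = alpha
        self.var_floor = var_floor

    def fit(self, train: Dataset, validation: Dataset | None = None) -> "NaiveBayesClassifier":
        C = train.schema.n_classes
        n = train.n
        self._log_priors = np.full(C, -np.inf)
        counts = train.class_counts()
        nz = counts > 0
        self._log_priors[nz] = np.log(counts[nz] / n)

        # per-feature conditional tables / Gaussian moments
        self._cat_cols: list[int] = []
        self._cat_codes: list[np.ndarray] = []
        self._cat_logp: list[np.ndarray] = []  # (C, n_codes)
        self._num_cols: list[int] = []
        num_mean, num_var = [], []
        for j, spec in enumerate(train.schema):
            col = train.values[:, j]
            if spec.is_categorical:
                codes = np.asarray(spec.codes, dtype=float)
                table = np.zeros((C, codes.size))
                for c in range(C):
                    mask = train.labels == c + 1
                    n_c = mask.sum()
                    code_counts = (col[mask, None] == codes[None, :]).sum(axis=0)
                    denom = n_c + self.alpha * codes.size
                    with np.errstate(divide="ignore"):
                        table[c] = np.log(
                            np.where(denom > 0, (code_counts + self.alpha) / max(denom, 1e-300), 0.0)
                        )
                self._cat_cols.append(j)
                self._cat_codes.append(codes)
                self._cat_logp.append(table)
            else:
                mean = np.zeros(C)
                var = np.full(C, self.var_floor)
                for c in range(C):
                    mask = train.labels == c + 1
                    if mask.any():
                        mean[c] = col[mask].mean()
                        var[c] = max(col[mask].var(), self.var_floor)
                self._num_cols.append(j)
                num_mean.append(mean)
                num_var.append(var)
        self._num_mean = np.array(num_mean) if num_mean else np.zeros((0, C))
        self._num_var = np.array(num_var) if num_var else np.ones((0, C))
        self._remember_training(train)
        return self

    def log_posterior(self, X) -> np.ndarray:
        """Unnormalized log posterior per class, (n, C)."""
        self._check_fitted()
        X = self._as_matrix(X)
        n = X.shape[0]
        ll = np.tile(self._log_priors, (n, 1))
        for j, codes, table in zip(self._cat_cols, self._cat_codes, self._cat_logp):
            idx = np.argmax(X[:, j, None] == codes[None, :], axis=1)
            known = (X[:, j, None] == codes[None, :]).any(axis=1)
            contrib = table[:, idx].T  # (n, C)
            # unseen codes contribute nothing (uninformative) rather than -inf
            ll += np.where(known[:, None], contrib, 0.0)
        if self._num_cols:
            x = X[:, self._num_cols]  # (n, f)
            mean = self._num_mean[None, :, :]  # (1, f, C)
            var = self._num_var[None, :, :]
            z = (x[:, :, None] - mean) ** 2 / var
            ll += (-0.5 * (np.log(2 * np.pi * var) + z)).sum(axis=1)
        return ll

    def posterior(self, X) -> np.ndarray:
        """Normalized class posterior probabilities, (n, C)."""
        ll = self.log_posterior(X)
        ll -= ll.max(axis=1, keepdims=True)
        p = np.exp(ll)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.log_posterior(X), axis=1) + 1
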