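"""Adaptive neuro-fuzzy inference system (first-order Sugeno) classifier.

A grid-partitioned fuzzy rule base with Gaussian membership functions is
fitted as a regressor of the integer class label: with ``m`` membership
functions per input and ``p`` inputs, all ``m^p`` conjunctive rules are
formed, each with a first-order (affine) consequent. Training is the
classic hybrid scheme, alternating per epoch:

1. consequent coefficients by (lightly ridge-stabilized) least squares
   with the premises frozen;
2. one gradient-descent step on the premise centers and spreads.

A validation set drives early stopping (best-validation parameters kept).
The predicted class is the admissible label nearest to the numeric
output, ties toward the lower label. Since the fuzzy system regresses a
single number onto an ordinal encoding of the classes, only modest
classification performance should be expected — the method is included as
a regression-style baseline.
"""

from __future__ import annotations

import numpy as np

from ..dataset import Dataset
from .base import BaseClassifier, ClassifierError


class ANFISClassifier(BaseClassifier):
    kind = "anfis"
    requires_validation = True

    def __init__(
        self,
        n_mf: int = 2,
        max_rules: int = 1024,
        max_epochs: int = 15,
        patience: int | None = 5,
        learning_rate: float = 0.05,
        ridge: float = 1e-6,
        seed: int = 0,
    ):
        if n_mf < 2:
            raise ClassifierError("need at least 2 membership functions per input")
        self.n_mf = n_mf
        self.max_rules = max_rules
        self.max_epochs = max_epochs
        self.patience = patience
        self.learning_rate = learning_rate
        self.ridge = ridge
        self.seed = seed

    # -- membership machinery -------------------------------------------
    def _memberships(self, X: np.ndarray) -> np.ndarray:
        """(n, p, m) Gaussian membership degrees."""
        z = (X[:, :, None] - self._centers[None, :, :]) / self._sigmas[None, :, :]
        return np.exp(-0.5 * z**2)

    def _firing(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu = self._memberships(X)  # (n, p, m)
        p = X.shape[1]
        w = mu[:, np.arange(p)[None, :], self._rules].prod(axis=2)  # (n, R)
        total = w.sum(axis=1, keepdims=True)
        total = np.where(total <= 1e-300, 1e-300, total)
        return w, w / total

    def _design(self, X: np.ndarray, wbar: np.ndarray) -> np.ndarray:
        n, p = X.shape
        ext = np.column_stack([X, np.ones(n)])  # (n, p+1)
        D = wbar[:, :, None] * ext[:, None, :]  # (n, R, p+1)
        return D.reshape(n, -1)

    def _solve_consequents(self, X: np.ndarray, t: np.ndarray, wbar: np.ndarray) -> np.ndarray:
        D = self._design(X, wbar)
        A = D.T @ D + self.ridge * np.eye(D.shape[1])
        return np.linalg.solve(A, D.T @ t)

    def _output(self, X: np.ndarray) -> np.ndarray:
        _, wbar = self._firing(X)
        return self._design(X, wbar) @ self._theta

    # -- training --------------------------------------------------------
    def fit(self, train: Dataset, validation: Dataset | None = None) -> "ANFISClassifier":
        if self.patience is not None and (validation is None or validation.n == 0):
            raise ClassifierError("early stopping requires a non-empty validation set")
        X = train.values
        t = train.labels.astype(float)
        n, p = X.shape
        n_rules = self.n_mf**p
        if n_rules > self.max_rules:
            raise ClassifierError(
                f"{n_rules} rules ({self.n_mf}^{p}) exceed the cap {self.max_rules}; "
                "reduce the input feature subset or the membership count"
            )
        # grid premises: centers evenly spaced over each input's range
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        grid = np.linspace(0.0, 1.0, self.n_mf)
        self._centers = lo[:, None] + span[:, None] * grid[None, :]
        self._sigmas = np.tile((span / (2.0 * max(self.n_mf - 1, 1)))[:, None], (1, self.n_mf))
        self._sigmas = np.maximum(self._sigmas, 1e-3)
        self._rules = np.stack(
            np.meshgrid(*[np.arange(self.n_mf)] * p, indexing="ij"), axis=-1
        ).reshape(-1, p)

        Xv = validation.values if validation is not None and validation.n else None
        tv = validation.labels.astype(float) if Xv is not None else None
        best = (np.inf, None)
        stale = 0
        for _ in range(self.max_epochs):
            w, wbar = self._firing(X)
            self._theta = self._solve_consequents(X, t, wbar)
            if Xv is not None:
                err = float(((self._output(Xv) - tv) ** 2).mean())
                if err < best[0] - 1e-12:
                    best = (err, (self._centers.copy(), self._sigmas.copy(), self._theta.copy()))
                    stale = 0
                elif self.patience is not None:
                    stale += 1
                    if stale >= self.patience:
                        break
            self._premise_step(X, t)
        if Xv is not None and best[1] is not None:
            self._centers, self._sigmas, self._theta = best[1]
        else:
            _, wbar = self._firing(X)
            self._theta = self._solve_consequents(X, t, wbar)
        self._remember_training(train)
        return self

    def _premise_step(self, X: np.ndarray, t: np.ndarray) -> None:
        """One gradient-descent step on Gaussian centers and spreads."""
        n, p = X.shape
        mu = self._memberships(X)
        w = mu[:, np.arange(p)[None, :], self._rules].prod(axis=2)
        W = np.maximum(w.sum(axis=1, keepdims=True), 1e-300)
        wbar = w / W
        ext = np.column_stack([X, np.ones(n)])
        theta = self._theta.reshape(-1, p + 1)  # (R, p+1)
        f = ext @ theta.T  # (n, R) rule outputs
        y = (wbar * f).sum(axis=1)
        resid = (y - t) / n  # (n,)
        # dE/dw_r = resid * (f_r - y) / W
        dw = resid[:, None] * (f - y[:, None]) / W  # (n, R)
        grad_c = np.zeros_like(self._centers)
        grad_s = np.zeros_like(self._sigmas)
        for i in range(p):
            zc = (X[:, i, None] - self._centers[None, i, self._rules[:, i]]) / (
                self._sigmas[None, i, self._rules[:, i]] ** 2
            )  # (n, R): (x - c)/sigma^2 for each rule's MF on input i
            contrib_c = dw * w * zc
            contrib_s = dw * w * zc**2 * self._sigmas[None, i, self._rules[:, i]]
            for j in range(self.n_mf):
                mask = self._rules[:, i] == j
                grad_c[i, j] = contrib_c[:, mask].sum()
                grad_s[i, j] = contrib_s[:, mask].sum()
        self._centers -= self.learning_rate * grad_c
        self._sigmas = np.maximum(self._sigmas - self.learning_rate * grad_s, 1e-3)

    # -- prediction ------------------------------------------------------
    def regression_output(self, X) -> np.ndarray:
        self._check_fitted()
        return self._output(self._as_matrix(X))

    def predict(self, X) -> np.ndarray:
        out = self.regression_output(X)
        labels = np.arange(1, self._n_classes + 1, dtype=float)
        # nearest admissible label; argmin's first hit favors the lower label
        return np.argmin(np.abs(out[:, None] - labels[None, :]), axis=1) + 1
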