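"""Generalized-linear-model classifier (one-vs-rest, IRLS).

Each class is fitted against a one-hot target by a GLM with intercept; a
query is assigned the class whose fitted mean response is largest. Four
distribution/link pairs are supported:

========  ==================  ==============  ===============
family    link eta = g(mu)    variance V(mu)  inverse link
========  ==================  ==============  ===============
normal    mu                  1               eta
inv_gauss mu^-2               mu^3            eta^-1/2
poisson   log(mu)             mu              exp(eta)
gamma     mu^-1               mu^2            eta^-1
========  ==================  ==============  ===============

The normal/identity pair reduces to plain least squares. The remaining
links are fitted by iteratively reweighted least squares with the mean
clamped to ``[1e-6, 1 - 1e-6]`` before link evaluation, since one-hot
targets sit exactly on the boundary of these links' domains.
"""

from __future__ import annotations

import numpy as np

from ..dataset import Dataset
from .base import BaseClassifier, ClassifierError

DISTRIBUTIONS = ("normal", "inverse_gaussian", "poisson", "gamma")

_MU_LO, _MU_HI = 1e-6, 1.0 - 1e-6


def _link(mu: np.ndarray, dist: str) -> np.ndarray:
    if dist == "normal":
        return mu
    if dist == "poisson":
        return np.log(mu)
    if dist == "gamma":
        return 1.0 / mu
    if dist == "inverse_gaussian":
        return mu**-2
    raise ClassifierError(f"unknown distribution {dist!r}")


def _inv_link(eta: np.ndarray, dist: str) -> np.ndarray:
    if dist == "normal":
        return eta
    if dist == "poisson":
        return np.exp(np.clip(eta, -30, 30))
    if dist == "gamma":
        return 1.0 / np.where(np.abs(eta) < 1e-12, 1e-12, eta)
    if dist == "inverse_gaussian":
        eta = np.maximum(eta, 1e-12)
        return eta**-0.5
    raise ClassifierError(f"unknown distribution {dist!r}")


def _link_deriv(mu: np.ndarray, dist: str) -> np.ndarray:
    """d eta / d mu."""
    if dist == "normal":
        return np.ones_like(mu)
    if dist == "poisson":
        return 1.0 / mu
    if dist == "gamma":
        return -(mu**-2)
    if dist == "inverse_gaussian":
        return -2.0 * mu**-3
    raise ClassifierError(f"unknown distribution {dist!r}")


def _variance(mu: np.ndarray, dist: str) -> np.ndarray:
    if dist == "normal":
        return np.ones_like(mu)
    if dist == "poisson":
        return mu
    if dist == "gamma":
        return mu**2
    if dist == "inverse_gaussian":
        return mu**3
    raise ClassifierError(f"unknown distribution {dist!r}")


def _check_design(design: np.ndarray, names) -> None:
    """Reject rank-deficient designs, naming the collinear columns."""
    unique = np.unique(design, axis=0)
    rank = np.linalg.matrix_rank(unique)
    if rank < design.shape[1]:
        _, r = np.linalg.qr(unique)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(unique.shape) * np.finfo(float).eps
        bad = [
            names[j - 1] if j > 0 else "intercept"
            for j in np.nonzero(diag <= tol)[0]
        ]
        raise ClassifierError(f"singular design; collinear columns: {bad}")


class GLMClassifier(BaseClassifier):
    """One-vs-rest GLM with argmax-of-fitted-means decision rule."""

    kind = "glm"

    def __init__(self, distribution: str = "normal", max_iter: int = 50, tol: float = 1e-10):
        if distribution not in DISTRIBUTIONS:
            raise ClassifierError(
                f"distribution must be one of {DISTRIBUTIONS}, got {distribution!r}"
            )
        self.distribution = distribution
        self.max_iter = max_iter
        self.tol = tol

    @property
    def link(self) -> str:
        return {
            "normal": "identity",
            "poisson": "log",
            "gamma": "reciprocal",
            "inverse_gaussian": "inverse_squared",
        }[self.distribution]

    def fit(self, train: Dataset, validation: Dataset | None = None) -> "GLMClassifier":
        X = np.column_stack([np.ones(train.n), train.values])
        _check_design(X, list(train.schema.names))
        C = train.schema.n_classes
        self._coef = np.zeros((C, X.shape[1]))
        for c in range(C):
            y = (train.labels == c + 1).astype(float)
            self._coef[c] = self._fit_one(X, y)
        self._remember_training(train)
        return self

    def _fit_one(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        dist = self.distribution
        if dist == "normal":
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return beta
        # IRLS from a boundary-safe starting mean
        mu = np.clip((y + y.mean()) / 2.0, _MU_LO, _MU_HI)
        beta = np.zeros(X.shape[1])
        for _ in range(self.max_iter):
            eta = _link(mu, dist)
            gprime = _link_deriv(mu, dist)
            z = eta + (y - mu) * gprime
            w = 1.0 / (_variance(mu, dist) * gprime**2)
            sw = np.sqrt(w)
            beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
            mu = np.clip(_inv_link(X @ beta_new, dist), _MU_LO, _MU_HI)
            if np.max(np.abs(beta_new - beta)) < self.tol:
                beta = beta_new
                break
            beta = beta_new
        return beta

    def class_scores(self, X) -> np.ndarray:
        """Fitted mean response of each one-vs-rest model, (n, C)."""
        self._check_fitted()
        X = self._as_matrix(X)
        design = np.column_stack([np.ones(X.shape[0]), X])
        eta = design @ self._coef.T
        return _inv_link(eta, self.distribution)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.class_scores(X), axis=1) + 1
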