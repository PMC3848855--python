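"""Single-hidden-layer perceptron trained by backpropagation.

Classic formulation: logistic sigmoid activations on the hidden and
output layers, one-hot targets, squared-error loss, full-batch gradient
descent with momentum. Training stops at ``max_epochs`` or when the
validation error has not improved for ``patience`` consecutive epochs;
the returned weights are those with the best validation error seen. The
decision rule is the argmax over the output activations.
"""

from __future__ import annotations

import numpy as np

from ..dataset import Dataset
from .base import BaseClassifier, ClassifierError

# hidden-node search grid used by default during model selection
DEFAULT_HIDDEN_GRID = tuple(range(2, 14))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


class MLPClassifier(BaseClassifier):
    kind = "mlp"
    requires_validation = True

    def __init__(
        self,
        n_hidden: int = 9,
        learning_rate: float = 0.5,
        momentum: float = 0.9,
        max_epochs: int = 400,
        patience: int | None = 30,
        seed: int = 0,
    ):
        if n_hidden < 1:
            raise ClassifierError("hidden node count must be >= 1")
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed

    def fit(self, train: Dataset, validation: Dataset | None = None) -> "MLPClassifier":
        if self.patience is not None and (validation is None or validation.n == 0):
            raise ClassifierError("early stopping requires a non-empty validation set")
        rng = np.random.default_rng(self.seed)
        X = train.values
        C = train.schema.n_classes
        T = np.eye(C)[train.labels - 1]
        n, p = X.shape

        W1 = rng.normal(0.0, 1.0 / np.sqrt(p + 1), size=(p, self.n_hidden))
        b1 = np.zeros(self.n_hidden)
        W2 = rng.normal(0.0, 1.0 / np.sqrt(self.n_hidden + 1), size=(self.n_hidden, C))
        b2 = np.zeros(C)
        vW1 = np.zeros_like(W1); vb1 = np.zeros_like(b1)
        vW2 = np.zeros_like(W2); vb2 = np.zeros_like(b2)

        if validation is not None and validation.n > 0:
            Xv = validation.values
            Tv = np.eye(C)[validation.labels - 1]
        else:
            Xv = Tv = None
        best = (np.inf, W1.copy(), b1.copy(), W2.copy(), b2.copy())
        stale = 0
        lr = self.learning_rate
        for _ in range(self.max_epochs):
            H = _sigmoid(X @ W1 + b1)
            O = _sigmoid(H @ W2 + b2)
            # squared-error deltas with sigmoid derivative
            dO = (O - T) * O * (1.0 - O) / n
            dH = (dO @ W2.T) * H * (1.0 - H)
            vW2 = self.momentum * vW2 - lr * (H.T @ dO)
            vb2 = self.momentum * vb2 - lr * dO.sum(axis=0)
            vW1 = self.momentum * vW1 - lr * (X.T @ dH)
            vb1 = self.momentum * vb1 - lr * dH.sum(axis=0)
            W2 += vW2; b2 += vb2; W1 += vW1; b1 += vb1

            if Xv is not None:
                Ov = _sigmoid(_sigmoid(Xv @ W1 + b1) @ W2 + b2)
                err = float(((Ov - Tv) ** 2).mean())
                if err < best[0] - 1e-12:
                    best = (err, W1.copy(), b1.copy(), W2.copy(), b2.copy())
                    stale = 0
                elif self.patience is not None:
                    stale += 1
                    if stale >= self.patience:
                        break
        if Xv is not None and np.isfinite(best[0]):
            _, W1, b1, W2, b2 = best
        self._W1, self._b1, self._W2, self._b2 = W1, b1, W2, b2
        self._remember_training(train)
        return self

    def activations(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._as_matrix(X)
        H = _sigmoid(X @ self._W1 + self._b1)
        return _sigmoid(H @ self._W2 + self._b2)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.activations(X), axis=1) + 1
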