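"""Shared train/classify contract for the classifier suite.

Every learner is an estimator with ``fit(train, validation=None)`` taking
:class:`~acsclass.dataset.Dataset` objects and ``predict(X)`` returning
one integer class label in ``1..C`` per row. Learners that tune against a
held-out sample (MLP, ANFIS) set ``requires_validation``. A functional
facade (:func:`train`, :func:`classify`) plus :class:`ClassifierSpec`
allows kind-by-name construction for configuration-driven pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from ..dataset import Dataset


class ClassifierError(ValueError):
    pass


class BaseClassifier:
    kind: str = "base"
    requires_validation: bool = False

    def fit(self, train: Dataset, validation: Dataset | None = None) -> "BaseClassifier":
        raise NotImplementedError

    def predict(self, X) -> np.ndarray:
        raise NotImplementedError

    # -- helpers shared by subclasses -----------------------------------
    def _check_fitted(self) -> None:
        if not getattr(self, "_fitted", False):
            raise ClassifierError(f"{self.kind} classifier is not fitted")

    def _as_matrix(self, X) -> np.ndarray:
        if isinstance(X, Dataset):
            X = X.values
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        width = getattr(self, "_n_features", None)
        if width is not None and X.shape[1] != width:
            raise ClassifierError(
                f"sample width {X.shape[1]} does not match training width {width}"
            )
        return X

    def _remember_training(self, train: Dataset) -> None:
        self._n_features = train.p
        self._n_classes = train.schema.n_classes
        self._fitted = True


@dataclass(frozen=True)
class ClassifierSpec:
    """Kind tag plus kind-specific hyperparameters and a seed."""

    kind: str
    params: Mapping[str, Any] = field(default_factory=dict)
    seed: int | None = None

    def replace_params(self, **updates) -> "ClassifierSpec":
        merged = {**dict(self.params), **updates}
        return ClassifierSpec(self.kind, merged, self.seed)


def make_classifier(spec: ClassifierSpec) -> BaseClassifier:
    """Instantiate the learner named by ``spec.kind``."""
    from . import REGISTRY

    if spec.kind not in REGISTRY:
        raise ClassifierError(
            f"unknown classifier kind {spec.kind!r}; known: {sorted(REGISTRY)}"
        )
    cls = REGISTRY[spec.kind]
    kwargs = dict(spec.params)
    if spec.seed is not None and "seed" in cls.__init__.__code__.co_varnames:
        kwargs.setdefault("seed", spec.seed)
    return cls(**kwargs)


def train(spec: ClassifierSpec, train_data: Dataset, validation: Dataset | None = None) -> BaseClassifier:
    """Fit a fresh learner of the specified kind."""
    model = make_classifier(spec)
    if model.requires_validation and validation is None:
        raise ClassifierError(f"{spec.kind} requires a validation set")
    return model.fit(train_data, validation)


def classify(model: BaseClassifier, samples) -> np.ndarray:
    """Predict one label in 1..C per sample row (empty input -> empty vector)."""
    samples = np.asarray(samples.values if isinstance(samples, Dataset) else samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[None, :]
    if samples.shape[0] == 0:
        return np.zeros(0, dtype=int)
    return model.predict(samples)
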