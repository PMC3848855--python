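"""Structured-text (JSON) serialization of trained models.

``save_model`` captures a fitted learner's kind tag, constructor
hyperparameters and fitted parameter arrays; ``load_model`` rebuilds an
equivalent model whose predictions are identical. Arrays round-trip
through nested lists with an explicit dtype tag; ID3 trees serialize
recursively.
"""

from __future__ import annotations

import inspect
import json

import numpy as np

from .base import BaseClassifier, ClassifierError
from .tree import ID3Classifier, _Node
from . import REGISTRY

# fitted state captured per kind (beyond the common bookkeeping)
_STATE_ATTRS: dict[str, tuple[str, ...]] = {
    "glm": ("_coef",),
    "knn": ("_X", "_y"),
    "naive_bayes": (
        "_log_priors", "_cat_cols", "_cat_codes", "_cat_logp",
        "_num_cols", "_num_mean", "_num_var",
    ),
    "id3": ("_categorical",),
    "bagging_id3": (),
    "mlp": ("_W1", "_b1", "_W2", "_b2"),
    "rbf": ("_centers", "_spreads", "_weights"),
    "anfis": ("_centers", "_sigmas", "_rules", "_theta"),
}
_COMMON_ATTRS = ("_n_features", "_n_classes")


def _encode(value):
    if isinstance(value, np.ndarray):
        return {"__array__": value.tolist(), "dtype": str(value.dtype)}
    if isinstance(value, (np.integer, np.floating)):
        return value.item()
    if isinstance(value, list):
        return [_encode(v) for v in value]
    return value


def _decode(value):
    if isinstance(value, dict) and "__array__" in value:
        return np.array(value["__array__"], dtype=value["dtype"])
    if isinstance(value, list):
        return [_decode(v) for v in value]
    return value


def _node_to_dict(node: _Node) -> dict:
    d = {"majority": node.majority}
    if node.column is not None:
        d["column"] = node.column
        if node.categorical:
            d["branches"] = {
                str(code): _node_to_dict(child) for code, child in node.branches.items()
            }
        else:
            d["threshold"] = node.threshold
            d["left"] = _node_to_dict(node.left)
            d["right"] = _node_to_dict(node.right)
    return d


def _node_from_dict(d: dict) -> _Node:
    node = _Node(majority=d["majority"])
    if "column" in d:
        node.column = d["column"]
        if "branches" in d:
            node.categorical = True
            node.branches = {
                float(code): _node_from_dict(child)
                for code, child in d["branches"].items()
            }
        else:
            node.threshold = d["threshold"]
            node.left = _node_from_dict(d["left"])
            node.right = _node_from_dict(d["right"])
    return node


def _hyperparams(model: BaseClassifier) -> dict:
    names = [
        p for p in inspect.signature(type(model).__init__).parameters if p != "self"
    ]
    return {name: _encode(getattr(model, name)) for name in names}


def save_model(model: BaseClassifier) -> str:
    """Serialize a fitted model to a JSON document."""
    if not getattr(model, "_fitted", False):
        raise ClassifierError("cannot serialize an unfitted model")
    kind = model.kind
    if kind not in _STATE_ATTRS:
        raise ClassifierError(f"unknown model kind {kind!r}")
    state = {a: _encode(getattr(model, a)) for a in _STATE_ATTRS[kind] + _COMMON_ATTRS}
    if kind == "id3":
        state["_root"] = _node_to_dict(model._root)
    elif kind == "bagging_id3":
        state["trees"] = [
            {"_categorical": _encode(t._categorical), "_root": _node_to_dict(t._root),
             "_n_features": t._n_features, "_n_classes": t._n_classes}
            for t in model._trees
        ]
    return json.dumps({"kind": kind, "hyperparams": _hyperparams(model), "state": state},
                      indent=1)


def load_model(text: str) -> BaseClassifier:
    """Rebuild a model saved by :func:`save_model`."""
    doc = json.loads(text)
    kind = doc["kind"]
    if kind not in REGISTRY:
        raise ClassifierError(f"unknown model kind {kind!r}")
    model = REGISTRY[kind](**{k: _decode(v) for k, v in doc["hyperparams"].items()})
    state = doc["state"]
    for attr in _STATE_ATTRS[kind] + _COMMON_ATTRS:
        setattr(model, attr, _decode(state[attr]))
    if kind == "id3":
        model._root = _node_from_dict(state["_root"])
    elif kind == "bagging_id3":
        trees = []
        for td in state["trees"]:
            tree = ID3Classifier(
                model.min_samples_split, model.max_depth
            )
            tree._categorical = _decode(td["_categorical"])
            tree._root = _node_from_dict(td["_root"])
            tree._n_features = td["_n_features"]
            tree._n_classes = td["_n_classes"]
            tree._fitted = True
            trees.append(tree)
        model._trees = trees
    model._fitted = True
    return model
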