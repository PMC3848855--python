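"""Clinical feature schemas for mixed-type tabular datasets.

A schema declares, for every feature, its measurement scale — ``nominal``,
``ordinal`` or ``ratio`` — and, for the categorical scales, the set of
allowed integer codes. Categorical features are used downstream as their
integer codes (no one-hot expansion); ratio features are continuous and are
min-max rescaled to a target interval (``[-1, 1]`` by default) before
modelling.

A default 40-feature acute coronary syndrome admission schema with four
outcome classes (STEMI, NSTEMI, UA, Other) is bundled and returned by
:func:`default_schema`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import yaml

CATEGORICAL_SCALES = ("nominal", "ordinal")
VALID_SCALES = CATEGORICAL_SCALES + ("ratio",)


class SchemaError(ValueError):
    """Raised for malformed schema configurations."""


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of a single clinical feature.

    Parameters
    ----------
    label : int
        Unique integer identifier of the feature within its schema.
    name : str
        Human-readable feature name (also the dataset column header).
    scale : {"nominal", "ordinal", "ratio"}
        Measurement scale. Nominal and ordinal features take values from
        ``codes``; ratio features are continuous.
    codes : tuple of int, optional
        Ordered allowed codes; required for categorical scales, forbidden
        for ratio features.
    target_range : tuple of float
        Closed interval ratio features are normalized into.
    """

    label: int
    name: str
    scale: str
    codes: tuple[int, ...] | None = None
    target_range: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise SchemaError(
                f"feature {self.label} ({self.name!r}): unknown scale {self.scale!r}"
            )
        if self.is_categorical:
            if not self.codes:
                raise SchemaError(
                    f"feature {self.label} ({self.name!r}): categorical feature "
                    "must declare a non-empty code set"
                )
        elif self.codes:
            raise SchemaError(
                f"feature {self.label} ({self.name!r}): ratio feature must not "
                "declare codes"
            )

    @property
    def is_categorical(self) -> bool:
        return self.scale in CATEGORICAL_SCALES

    @property
    def is_ratio(self) -> bool:
        return self.scale == "ratio"


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered collection of :class:`FeatureSpec` plus the class labelling."""

    features: tuple[FeatureSpec, ...]
    n_classes: int = 4
    class_names: tuple[str, ...] = ("STEMI", "NSTEMI", "UA", "Other")

    def __post_init__(self) -> None:
        if not self.features:
            raise SchemaError("schema declares no features")
        labels = [f.label for f in self.features]
        seen: set[int] = set()
        for lab in labels:
            if lab in seen:
                raise SchemaError(f"duplicate feature label {lab}")
            seen.add(lab)
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate feature names {dup}")
        if self.n_classes < 1:
            raise SchemaError("n_classes must be positive")
        if len(self.class_names) != self.n_classes:
            raise SchemaError(
                f"{len(self.class_names)} class names for {self.n_classes} classes"
            )

    # -- lookups ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(f.label for f in self.features)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    @property
    def ratio_labels(self) -> tuple[int, ...]:
        return tuple(f.label for f in self.features if f.is_ratio)

    @property
    def categorical_labels(self) -> tuple[int, ...]:
        return tuple(f.label for f in self.features if f.is_categorical)

    def feature(self, label: int) -> FeatureSpec:
        for f in self.features:
            if f.label == label:
                return f
        raise KeyError(f"no feature with label {label}")

    def column_of(self, label: int) -> int:
        """Column index of a feature label in the dataset value matrix."""
        for i, f in enumerate(self.features):
            if f.label == label:
                return i
        raise KeyError(f"no feature with label {label}")

    def columns_of(self, labels: Iterable[int]) -> list[int]:
        return [self.column_of(lab) for lab in labels]

    def subset(self, labels: Sequence[int]) -> "FeatureSchema":
        """Schema restricted to ``labels``, keeping the original order."""
        keep = set(labels)
        feats = tuple(f for f in self.features if f.label in keep)
        missing = keep - {f.label for f in feats}
        if missing:
            raise KeyError(f"labels not in schema: {sorted(missing)}")
        return FeatureSchema(feats, self.n_classes, self.class_names)


def _parse_feature(entry: dict) -> FeatureSpec:
    try:
        label = int(entry["label"])
        name = str(entry["name"])
        scale = str(entry["scale"])
    except KeyError as exc:
        raise SchemaError(f"feature entry {entry!r} missing key {exc}") from exc
    codes = entry.get("codes")
    if codes is not None:
        codes = tuple(int(c) for c in codes)
    rng = entry.get("range", (-1.0, 1.0))
    return FeatureSpec(label, name, scale, codes, (float(rng[0]), float(rng[1])))


def load_schema(config_text: str) -> FeatureSchema:
    """Parse a YAML schema configuration into a :class:`FeatureSchema`.

    The config is a mapping with keys ``features`` (list of per-feature
    entries ``{label, name, scale, codes?, range?}``), ``n_classes`` and
    ``class_names``.
    """
    doc = yaml.safe_load(config_text)
    if not isinstance(doc, dict) or "features" not in doc:
        raise SchemaError("schema config must be a mapping with a 'features' list")
    entries = doc["features"] or []
    features = tuple(_parse_feature(e) for e in entries)
    n_classes = int(doc.get("n_classes", 4))
    class_names = tuple(doc.get("class_names", ("STEMI", "NSTEMI", "UA", "Other")))
    return FeatureSchema(features, n_classes, class_names)


def default_schema() -> FeatureSchema:
    """The bundled 40-feature ACS admission schema (4 outcome classes)."""
    text = resources.files("acsclass.data").joinpath("acs40.yaml").read_text()
    return load_schema(text)
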