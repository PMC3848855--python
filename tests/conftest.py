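import numpy as np
import pytest

from acsclass.schema import FeatureSchema, FeatureSpec


def make_schema(specs, n_classes=4, class_names=None):
    """Build a schema from (label, name, scale[, codes]) tuples."""
    feats = []
    for s in specs:
        label, name, scale = s[0], s[1], s[2]
        codes = tuple(s[3]) if len(s) > 3 else None
        feats.append(FeatureSpec(label, name, scale, codes))
    if class_names is None:
        class_names = tuple(f"C{i + 1}" for i in range(n_classes))
    return FeatureSchema(tuple(feats), n_classes, tuple(class_names))


@pytest.fixture
def ratio_schema():
    """One continuous feature, two classes."""
    return make_schema([(1, "x", "ratio")], n_classes=2)


@pytest.fixture
def mixed_schema():
    """One binary, one continuous feature, two classes."""
    return make_schema([(1, "flag", "nominal", (1, 2)), (2, "x", "ratio")], n_classes=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
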