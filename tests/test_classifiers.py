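"""Unit and oracle tests for the eight from-scratch learners."""

import numpy as np
import pytest

from acsclass.classifiers import (
    ANFISClassifier,
    BaggingID3Classifier,
    ClassifierError,
    ClassifierSpec,
    GLMClassifier,
    ID3Classifier,
    KNNClassifier,
    MLPClassifier,
    NaiveBayesClassifier,
    RBFClassifier,
    classify,
    make_classifier,
)
from acsclass.classifiers.tree import best_split, entropy_bits
from acsclass.dataset import Dataset

from conftest import make_schema


def ds_1d(xs, ys, n_classes=2):
    schema = make_schema([(1, "x", "ratio")], n_classes=n_classes)
    return Dataset(np.asarray(xs, float).reshape(-1, 1), ys, schema)


def ds_cat(cols, ys, codes_per_col, n_classes=2):
    specs = [
        (j + 1, f"f{j + 1}", "nominal", codes) for j, codes in enumerate(codes_per_col)
    ]
    schema = make_schema(specs, n_classes=n_classes)
    return Dataset(np.asarray(cols, float), ys, schema)


class TestGLM:
    def test_link_tags(self):
        assert GLMClassifier("poisson").link == "log"
        assert GLMClassifier("normal").link == "identity"
        assert GLMClassifier("gamma").link == "reciprocal"
        assert GLMClassifier("inverse_gaussian").link == "inverse_squared"

    def test_normal_closed_form_two_point(self):
        # classes at x = -1 and x = +1, 5 copies each: the least-squares
        # one-vs-rest scores are s1 = (1 - x)/2 and s2 = (1 + x)/2
        ds = ds_1d([-1] * 5 + [1] * 5, [1] * 5 + [2] * 5)
        model = GLMClassifier("normal").fit(ds)
        scores = model.class_scores(np.array([[0.6]]))
        np.testing.assert_allclose(scores[0], [(1 - 0.6) / 2, (1 + 0.6) / 2], atol=1e-10)
        assert model.predict(np.array([[0.6]]))[0] == 2

    def test_normal_matches_lstsq_on_random_design(self, rng):
        n, p = 40, 3
        X = rng.normal(size=(n, p))
        y = rng.integers(1, 4, size=n)
        schema = make_schema([(j + 1, f"x{j}", "ratio") for j in range(p)], n_classes=3)
        model = GLMClassifier("normal").fit(Dataset(X, y, schema))
        design = np.column_stack([np.ones(n), X])
        for c in range(3):
            beta, *_ = np.linalg.lstsq(design, (y == c + 1).astype(float), rcond=None)
            np.testing.assert_allclose(model._coef[c], beta, atol=1e-8)

    def test_irls_against_statsmodels_poisson(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 200
        X = rng.normal(size=(n, 2))
        y = rng.integers(1, 3, size=n)
        schema = make_schema([(1, "a", "ratio"), (2, "b", "ratio")], n_classes=2)
        model = GLMClassifier("poisson").fit(Dataset(X, y, schema))
        design = np.column_stack([np.ones(n), X])
        for c in range(2):
            target = (y == c + 1).astype(float)
            ref = sm.GLM(target, design, family=sm.families.Poisson()).fit()
            np.testing.assert_allclose(model._coef[c], ref.params, rtol=1e-4, atol=1e-5)

    def test_single_class_training(self):
        ds = ds_1d([0.0, 1.0, 2.0], [1, 1, 1], n_classes=2)
        model = GLMClassifier("normal").fit(ds)
        assert (model.predict(np.array([[5.0], [-3.0]])) == 1).all()

    def test_collinear_design_rejected(self):
        schema = make_schema([(1, "a", "ratio"), (2, "b", "ratio")], n_classes=2)
        X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [0.5, 1.0]])
        with pytest.raises(ClassifierError, match="collinear"):
            GLMClassifier("normal").fit(Dataset(X, [1, 2, 1, 2], schema))

    def test_unknown_distribution(self):
        with pytest.raises(ClassifierError):
            GLMClassifier("binomial")


class TestKNN:
    def test_three_neighbor_example(self):
        ds = ds_1d([0.0, 0.1, 1.0, 1.1], [1, 1, 2, 2])
        model = KNNClassifier(3).fit(ds)
        # neighbors of 0.05 are 0.0, 0.1 (class 1) and 1.0 (class 2)
        assert model.predict(np.array([[0.05]]))[0] == 1

    def test_zero_distance_neighbor(self):
        ds = ds_1d([0.0, 0.5, 1.0], [1, 2, 1])
        model = KNNClassifier(1).fit(ds)
        assert model.predict(np.array([[0.5]]))[0] == 2

    def test_default_k_is_seven(self):
        assert KNNClassifier().k == 7

    def test_even_or_nonpositive_k_rejected(self):
        with pytest.raises(ClassifierError):
            KNNClassifier(4)
        with pytest.raises(ClassifierError):
            KNNClassifier(0)

    def test_k_exceeding_n(self):
        with pytest.raises(ClassifierError, match="exceeds"):
            KNNClassifier(3).fit(ds_1d([0.0], [1]))

    def test_training_accuracy_one_at_k1(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.integers(1, 4, size=30)
        schema = make_schema([(j + 1, f"x{j}", "ratio") for j in range(3)], n_classes=3)
        ds = Dataset(X, y, schema)
        model = KNNClassifier(1).fit(ds)
        np.testing.assert_array_equal(model.predict(X), y)

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_agrees_with_brute_force_oracle(self, k, rng):
        """Independent oracle: full distance matrix + stable sort + replayed vote."""
        n, p, C = 120, 4, 4
        X = rng.normal(size=(n, p))
        y = rng.integers(1, C + 1, size=n)
        Q = rng.normal(size=(50, p))
        schema = make_schema([(j + 1, f"x{j}", "ratio") for j in range(p)], n_classes=C)
        model = KNNClassifier(k).fit(Dataset(X, y, schema))
        got = model.predict(Q)
        for qi, q in enumerate(Q):
            d = np.sqrt(((X - q) ** 2).sum(axis=1))
            order = sorted(range(n), key=lambda j: (d[j], j))[:k]
            labs = y[order]
            counts = {c: (labs == c).sum() for c in range(1, C + 1)}
            top = max(counts.values())
            tied = [c for c, v in counts.items() if v == top]
            best = min(tied, key=lambda c: (d[[order[i] for i in range(k) if labs[i] == c]].mean(), c))
            assert got[qi] == best


class TestNaiveBayes:
    def test_hand_bayes_posterior(self):
        # alpha=0: p(c1 | f=1) = 0.5*1 / (0.5*1 + 0.5*(1/3)) = 0.75
        ds = ds_cat([[1], [1], [1], [2], [2], [1]], [1, 1, 1, 2, 2, 2], [(1, 2)])
        model = NaiveBayesClassifier(alpha=0.0).fit(ds)
        post = model.posterior(np.array([[1.0]]))
        np.testing.assert_allclose(post[0], [0.75, 0.25])
        assert model.predict(np.array([[1.0]]))[0] == 1

    def test_variance_floor_keeps_likelihood_finite(self):
        ds = ds_1d([0.0, 0.0, 1.0, 1.0], [1, 1, 2, 2])
        model = NaiveBayesClassifier().fit(ds)
        assert model.predict(np.array([[0.1]]))[0] == 1
        assert np.isfinite(model.log_posterior(np.array([[0.1]]))).all()

    def test_identical_conditionals_fall_back_to_majority(self):
        ds = ds_cat([[1], [1], [1], [1], [1]], [1, 1, 1, 2, 2], [(1, 2)])
        model = NaiveBayesClassifier().fit(ds)
        assert model.predict(np.array([[1.0]]))[0] == 1

    def test_enumerated_bayes_oracle_categorical(self, rng):
        """Exhaustive Bayes computation on a small fully categorical problem."""
        n, C = 60, 3
        codes = [(1, 2), (1, 2, 3)]
        X = np.column_stack([rng.integers(1, len(c) + 1, size=n) for c in codes]).astype(float)
        y = rng.integers(1, C + 1, size=n)
        ds = ds_cat(X, y, codes, n_classes=C)
        alpha = 1.0
        model = NaiveBayesClassifier(alpha=alpha).fit(ds)
        for x1 in codes[0]:
            for x2 in codes[1]:
                joint = np.zeros(C)
                for c in range(1, C + 1):
                    nc = (y == c).sum()
                    prior = nc / n
                    p1 = ((X[y == c, 0] == x1).sum() + alpha) / (nc + alpha * 2)
                    p2 = ((X[y == c, 1] == x2).sum() + alpha) / (nc + alpha * 3)
                    joint[c - 1] = prior * p1 * p2
                expected = int(np.argmax(joint)) + 1
                got = model.predict(np.array([[x1, x2]], dtype=float))[0]
                assert got == expected


class TestID3:
    def test_perfect_categorical_split_gain_one_bit(self):
        ds = ds_cat([[1], [1], [2], [2]], [1, 1, 2, 2], [(1, 2)])
        gain, col, thr = best_split(ds.values, ds.labels, np.array([True]))
        assert gain == pytest.approx(1.0)
        assert col == 0 and thr is None
        model = ID3Classifier().fit(ds)
        np.testing.assert_array_equal(model.predict(ds.values), ds.labels)

    def test_pure_node_is_leaf(self):
        ds = ds_cat([[1], [2]], [1, 1], [(1, 2)])
        model = ID3Classifier().fit(ds)
        assert model._root.column is None
        assert model._root.majority == 1

    def test_continuous_threshold_midpoint(self):
        ds = ds_1d([0.1, 0.2, 0.8, 0.9], [1, 1, 2, 2])
        model = ID3Classifier().fit(ds)
        assert model._root.threshold == pytest.approx(0.5)
        np.testing.assert_array_equal(model.predict(ds.values), ds.labels)

    def test_root_split_matches_exhaustive_gain_scan(self, rng):
        """Oracle: enumerate every feature and midpoint threshold directly."""
        for trial in range(5):
            n = 40
            Xc = rng.integers(1, 4, size=(n, 1)).astype(float)
            Xr = rng.normal(size=(n, 1))
            X = np.column_stack([Xc, Xr])
            y = rng.integers(1, 4, size=n)
            base = entropy_bits(y)
            best_gain, best_key = -1.0, None
            # categorical feature 0
            cond = 0.0
            for code in np.unique(X[:, 0]):
                mask = X[:, 0] == code
                cond += mask.sum() / n * entropy_bits(y[mask])
            if len(np.unique(X[:, 0])) > 1 and base - cond > best_gain + 1e-12:
                best_gain, best_key = base - cond, (0, None)
            # continuous feature 1
            vals = np.unique(X[:, 1])
            for t in (vals[:-1] + vals[1:]) / 2:
                mask = X[:, 1] <= t
                cond = mask.sum() / n * entropy_bits(y[mask]) + (
                    (~mask).sum() / n * entropy_bits(y[~mask])
                )
                if base - cond > best_gain + 1e-12:
                    best_gain, best_key = base - cond, (1, t)
            gain, col, thr = best_split(X, y, np.array([True, False]))
            assert gain == pytest.approx(best_gain)
            assert (col, thr if thr is None else pytest.approx(thr)) == best_key

    def test_unseen_code_falls_through_to_majority(self):
        ds = ds_cat([[1], [1], [2]], [1, 1, 2], [(1, 2, 3)])
        model = ID3Classifier().fit(ds)
        assert model.predict(np.array([[3.0]]))[0] == 1


class TestBaggingID3:
    def test_single_class_unanimous(self):
        ds = ds_1d([0.0, 1.0, 2.0], [2, 2, 2])
        model = BaggingID3Classifier(n_estimators=5, seed=0).fit(ds)
        assert (model.predict(ds.values) == 2).all()

    def test_plurality_vote(self):
        ds = ds_1d([0.0, 1.0], [1, 2])
        model = BaggingID3Classifier(n_estimators=3, seed=0).fit(ds)

        class Stub:
            def __init__(self, lab):
                self.lab = lab

            def predict(self, X):
                return np.full(len(X), self.lab)

        model._trees = [Stub(1), Stub(1), Stub(2)]
        assert model.predict(np.array([[0.5]]))[0] == 1

    def test_identity_resample_b1_reduces_to_id3(self, rng):
        X = rng.normal(size=(40, 2))
        y = rng.integers(1, 3, size=40)
        schema = make_schema([(1, "a", "ratio"), (2, "b", "ratio")], n_classes=2)
        ds = Dataset(X, y, schema)
        bag = BaggingID3Classifier(n_estimators=1, seed=0, resample=False).fit(ds)
        tree = ID3Classifier().fit(ds)
        Q = rng.normal(size=(30, 2))
        np.testing.assert_array_equal(bag.predict(Q), tree.predict(Q))

    def test_seeded_reproducibility(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.integers(1, 3, size=30)
        schema = make_schema([(1, "a", "ratio"), (2, "b", "ratio")], n_classes=2)
        ds = Dataset(X, y, schema)
        Q = rng.normal(size=(20, 2))
        p1 = BaggingID3Classifier(n_estimators=7, seed=42).fit(ds).predict(Q)
        p2 = BaggingID3Classifier(n_estimators=7, seed=42).fit(ds).predict(Q)
        np.testing.assert_array_equal(p1, p2)


class TestMLP:
    def _sep_ds(self):
        xs = list(np.linspace(-1.5, -0.5, 10)) + list(np.linspace(0.5, 1.5, 10))
        ys = [1] * 10 + [2] * 10
        return ds_1d(xs, ys)

    def test_single_class_constant_prediction(self):
        ds = ds_1d([0.0, 0.3, 0.9, 0.5], [2, 2, 2, 2])
        model = MLPClassifier(n_hidden=2, seed=0, max_epochs=50, patience=None).fit(ds)
        assert (model.predict(np.array([[0.1], [0.8]])) == 2).all()

    def test_separable_data_reaches_training_accuracy_one(self):
        ds = self._sep_ds()
        model = MLPClassifier(
            n_hidden=2, seed=1, max_epochs=2000, learning_rate=1.0, patience=None
        ).fit(ds)
        assert (model.predict(ds.values) == ds.labels).all()

    def test_early_stopping_requires_validation(self):
        with pytest.raises(ClassifierError, match="validation"):
            MLPClassifier(n_hidden=2, patience=5).fit(self._sep_ds())

    def test_seeded_reproducibility_bitwise(self):
        ds = self._sep_ds()
        m1 = MLPClassifier(n_hidden=3, seed=9, max_epochs=100, patience=None).fit(ds)
        m2 = MLPClassifier(n_hidden=3, seed=9, max_epochs=100, patience=None).fit(ds)
        np.testing.assert_array_equal(m1._W1, m2._W1)
        np.testing.assert_array_equal(m1._W2, m2._W2)

    def test_default_hidden_grid(self):
        from acsclass.classifiers import DEFAULT_HIDDEN_GRID

        assert DEFAULT_HIDDEN_GRID == tuple(range(2, 14))


class TestRBF:
    def test_exact_interpolation_with_center_per_point(self):
        ds = ds_1d([0.0, 1.0, 2.0, 3.0], [1, 2, 1, 2])
        model = RBFClassifier(n_centers=4, ridge=0.0, seed=0).fit(ds)
        np.testing.assert_array_equal(model.predict(ds.values), ds.labels)

    def test_single_class_constant(self):
        ds = ds_1d([0.0, 1.0, 2.0], [1, 1, 1])
        model = RBFClassifier(n_centers=2, seed=0).fit(ds)
        assert (model.predict(np.array([[0.5], [1.5]])) == 1).all()

    def test_too_many_centers(self):
        ds = ds_1d([0.0, 0.0, 1.0], [1, 1, 2])
        with pytest.raises(ClassifierError, match="distinct"):
            RBFClassifier(n_centers=3, seed=0).fit(ds)

    def test_default_center_count(self):
        assert RBFClassifier().n_centers == 7

    def test_seeded_reproducibility_bitwise(self, rng):
        X = rng.normal(size=(40, 2))
        y = rng.integers(1, 4, size=40)
        schema = make_schema([(1, "a", "ratio"), (2, "b", "ratio")], n_classes=3)
        ds = Dataset(X, y, schema)
        m1 = RBFClassifier(n_centers=5, seed=3).fit(ds)
        m2 = RBFClassifier(n_centers=5, seed=3).fit(ds)
        np.testing.assert_array_equal(m1._centers, m2._centers)
        np.testing.assert_array_equal(m1._weights, m2._weights)


class TestANFIS:
    def test_constant_target_zero_error(self):
        ds = ds_1d([0.0, 0.5, 1.0, 1.5], [2, 2, 2, 2])
        model = ANFISClassifier(seed=0, patience=None, ridge=1e-12).fit(ds)
        out = model.regression_output(ds.values)
        np.testing.assert_allclose(out, 2.0, atol=1e-6)
        assert (model.predict(ds.values) == 2).all()

    def test_linear_target_consequent_least_squares(self):
        # y = 2x + 1 is inside the model class: every rule's affine
        # consequent can equal it, so the fit is exact on training points
        xs = np.linspace(0, 1, 9)
        ys = 2 * xs + 1
        schema = make_schema([(1, "x", "ratio")], n_classes=3)
        ds = Dataset(xs.reshape(-1, 1), np.clip(np.round(ys), 1, 3).astype(int), schema)
        model = ANFISClassifier(seed=0, patience=None, max_epochs=1, ridge=1e-10)
        model.fit(ds)
        # refit consequents against the exact linear target
        _, wbar = model._firing(ds.values)
        theta = model._solve_consequents(ds.values, ys, wbar)
        pred = model._design(ds.values, wbar) @ theta
        np.testing.assert_allclose(pred, ys, atol=1e-5)

    def test_rule_cap(self):
        schema = make_schema([(j + 1, f"x{j}", "ratio") for j in range(5)], n_classes=2)
        ds = Dataset(np.random.default_rng(0).normal(size=(20, 5)), [1, 2] * 10, schema)
        with pytest.raises(ClassifierError, match="cap"):
            ANFISClassifier(n_mf=4, max_rules=100, patience=None).fit(ds)

    def test_seeded_reproducibility_bitwise(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.integers(1, 3, size=30)
        schema = make_schema([(1, "a", "ratio"), (2, "b", "ratio")], n_classes=2)
        ds = Dataset(X, y, schema)
        m1 = ANFISClassifier(seed=5, patience=None, max_epochs=4).fit(ds)
        m2 = ANFISClassifier(seed=5, patience=None, max_epochs=4).fit(ds)
        np.testing.assert_array_equal(m1._theta, m2._theta)
        np.testing.assert_array_equal(m1._centers, m2._centers)


class TestClassifyContract:
    def test_empty_input_empty_output(self):
        ds = ds_1d([0.0, 1.0], [1, 2])
        model = KNNClassifier(1).fit(ds)
        assert classify(model, np.zeros((0, 1))).shape == (0,)

    def test_width_mismatch(self):
        ds = ds_1d([0.0, 1.0], [1, 2])
        model = KNNClassifier(1).fit(ds)
        with pytest.raises(ClassifierError, match="width"):
            classify(model, np.zeros((2, 3)))

    def test_repeat_query_deterministic(self):
        ds = ds_1d([0.0, 0.4, 1.0], [1, 2, 2])
        model = KNNClassifier(3).fit(ds)
        q = np.array([[0.3]])
        assert model.predict(q)[0] == model.predict(q)[0]

    def test_factory_by_kind(self):
        model = make_classifier(ClassifierSpec("knn", {"k": 3}))
        assert isinstance(model, KNNClassifier) and model.k == 3

    def test_unknown_kind(self):
        with pytest.raises(ClassifierError, match="unknown"):
            make_classifier(ClassifierSpec("svm"))
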