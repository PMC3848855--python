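"""Backward-elimination wrapper: oracle equivalence and search behavior."""

import itertools

import numpy as np
import pytest

from acsclass.dataset import Dataset
from acsclass.selection import (
    CandidateRecord,
    RoundRecord,
    SelectionError,
    SelectionTrace,
    _knn_accuracy_batch,
    _knn_accuracy_batch_numpy,
    backward_eliminate,
    best_subset,
    evaluate_subset,
    selection_splits,
)
from acsclass.synthetic import default_acs_config, generate_dataset

from conftest import make_schema


def planted_ds(n=60, seed=0):
    """Feature A determines the class; B and C are pure noise."""
    rng = np.random.default_rng(seed)
    y = rng.integers(1, 3, size=n)
    a = np.where(y == 1, 0.0, 1.0) + rng.normal(0, 0.05, size=n)
    b = rng.normal(size=n)
    c = rng.normal(size=n)
    schema = make_schema(
        [(1, "A", "ratio"), (2, "B", "ratio"), (3, "C", "ratio")], n_classes=2
    )
    return Dataset(np.column_stack([a, b, c]), y, schema)


class TestEvaluateSubset:
    def test_empty_subset_rejected(self):
        with pytest.raises(SelectionError):
            evaluate_subset(planted_ds(), [], k=1)

    def test_mean_over_reps_is_mean_of_single_splits(self):
        data = planted_ds()
        splits = selection_splits(data, reps=3, split_fraction=0.7, seed=5)
        singles = [
            evaluate_subset(data, [1, 2], k=1, splits=[s]) for s in splits
        ]
        combined = evaluate_subset(data, [1, 2], k=1, splits=splits)
        assert combined == pytest.approx(np.mean(singles))

    def test_k_larger_than_training_split(self):
        with pytest.raises(SelectionError, match="exceeds"):
            evaluate_subset(planted_ds(n=10), [1], k=9, reps=2)

    def test_deterministic_given_seed(self):
        data = planted_ds()
        a = evaluate_subset(data, [1, 3], k=3, reps=5, seed=7)
        b = evaluate_subset(data, [1, 3], k=3, reps=5, seed=7)
        assert a == b


class TestFastEvaluatorKernel:
    def test_numpy_and_jit_paths_agree(self, rng):
        """The jitted kernel and the numpy reference implement one rule."""
        for trial in range(5):
            D = rng.integers(0, 5, size=(6, 15, 40)).astype(np.float32)
            y_train = rng.integers(1, 5, size=40)
            y_test = rng.integers(1, 5, size=15)
            a = _knn_accuracy_batch(D, 3, y_train, y_test, 4)
            b = _knn_accuracy_batch_numpy(D, 3, y_train, y_test, 4)
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_matches_knn_classifier_on_integer_codes(self, rng):
        """Fast-path scores equal a direct KNNClassifier evaluation, ties included."""
        from acsclass.classifiers import KNNClassifier
        from conftest import make_schema as ms

        n_tr, n_te, p = 50, 20, 3
        X_tr = rng.integers(1, 3, size=(n_tr, p)).astype(float)
        X_te = rng.integers(1, 3, size=(n_te, p)).astype(float)
        y_tr = rng.integers(1, 4, size=n_tr)
        y_te = rng.integers(1, 4, size=n_te)
        D = np.zeros((1, n_te, n_tr), dtype=np.float32)
        for j in range(p):
            D[0] += (X_te[:, j, None] - X_tr[None, :, j]).astype(np.float32) ** 2
        fast = _knn_accuracy_batch(D, 5, y_tr, y_te, 3)[0]
        schema = ms([(j + 1, f"f{j}", "nominal", (1, 2)) for j in range(p)], n_classes=3)
        model = KNNClassifier(5).fit(Dataset(X_tr, y_tr, schema))
        direct = float(np.mean(model.predict(X_te) == y_te))
        assert fast == pytest.approx(direct, abs=1e-12)


class TestBackwardEliminate:
    def test_subset_size_decreases_by_one_per_round(self):
        data = planted_ds()
        trace = backward_eliminate(data, k_grid=(1, 3), reps=5, seed=0)
        for k in (1, 3):
            rounds = [r for r in trace.rounds if r.k == k]
            sizes = [len(r.parent_subset) for r in rounds]
            assert sizes == [3, 2]
            for r in rounds:
                assert len(r.chosen) == len(r.parent_subset) - 1

    def test_single_feature_dataset(self):
        data = planted_ds().select_features([1])
        trace = backward_eliminate(data, k_grid=(1,), reps=3, seed=0)
        assert trace.rounds == ()
        assert set(trace.full_set_accuracy) == {1}

    def test_replay_reproduces_accuracies(self):
        data = planted_ds()
        t1 = backward_eliminate(data, k_grid=(1,), reps=10, seed=3)
        t2 = backward_eliminate(data, k_grid=(1,), reps=10, seed=3)
        for r1, r2 in zip(t1.rounds, t2.rounds):
            assert r1.candidates == r2.candidates

    def test_planted_feature_recovered(self):
        data = planted_ds(n=60, seed=1)
        trace = backward_eliminate(data, k_grid=(1,), reps=20, seed=1)
        result = best_subset(trace)
        assert result.best_subset == (1,)
        assert result.best_accuracy > 0.95

    def test_greedy_matches_exhaustive_wrapper_oracle(self):
        """Every greedy accuracy and choice agrees with an independent
        exhaustive evaluation of all subsets on the same splits."""
        data = planted_ds(n=40, seed=2)
        reps, k = 10, 1
        trace = backward_eliminate(data, k_grid=(k,), reps=reps, seed=4)
        splits = selection_splits(data, reps, 0.7, 4)
        oracle = {
            subset: evaluate_subset(data, subset, k, splits=splits)
            for r in range(1, 4)
            for subset in itertools.combinations((1, 2, 3), r)
        }
        assert trace.full_set_accuracy[k] == pytest.approx(oracle[(1, 2, 3)], abs=1e-9)
        for rec in trace.rounds:
            for cand in rec.candidates:
                assert cand.mean_accuracy == pytest.approx(oracle[cand.subset], abs=1e-9)
            best_cand = max(
                rec.candidates, key=lambda cd: cd.mean_accuracy
            )
            assert rec.chosen_accuracy == pytest.approx(best_cand.mean_accuracy)
        # the global argmax matches the oracle's global argmax accuracy
        result = best_subset(trace)
        evaluated = [oracle[c.subset] for r in trace.rounds for c in r.candidates]
        evaluated.append(oracle[(1, 2, 3)])
        assert result.best_accuracy == pytest.approx(max(evaluated), abs=1e-9)


class TestBestSubset:
    def _trace(self, entries):
        rounds = []
        for i, (k, subset, acc) in enumerate(entries):
            rounds.append(
                RoundRecord(
                    k, i, tuple(subset) + (99,),
                    (CandidateRecord(tuple(subset), acc),),
                    tuple(subset), acc,
                )
            )
        return SelectionTrace(
            (1,), (1, 2, 3, 4, 5, 6, 7, 99), {1: 0.0}, tuple(rounds), 0, 1, 0.7
        )

    def test_unique_maximum(self):
        trace = self._trace([(1, (1, 2), 0.8), (1, (1,), 0.9)])
        res = best_subset(trace)
        assert res.best_subset == (1,) and res.best_accuracy == 0.9

    def test_tie_prefers_smaller_subset(self):
        trace = self._trace(
            [(1, (1, 2, 3, 4, 5, 6, 7), 0.9), (1, (1, 2, 3), 0.9)]
        )
        res = best_subset(trace)
        assert res.best_subset == (1, 2, 3)
        assert "tied" in res.tie_break


class TestRecoveryOnDefaultRegistry:
    def test_selected_subset_overlaps_planted_on_one_seed(self):
        """Smoke-scale recovery: the search lands on mostly planted features."""
        ds, truth = generate_dataset(default_acs_config(), 2)
        trace = backward_eliminate(ds, k_grid=(7,), reps=10, seed=2)
        result = best_subset(trace)
        planted, got = set(truth.informative), set(result.best_subset)
        jaccard = len(planted & got) / len(planted | got)
        assert jaccard >= 0.6
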