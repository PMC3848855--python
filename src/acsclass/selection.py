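"""k-NN-wrapped sequential backward-elimination feature selection.

The wrapper jointly optimizes the feature subset and the neighbor count
k: for every k in a grid, the search starts from the full feature set
and, per round, evaluates every leave-one-out candidate subset by the
mean test accuracy of a k-NN classifier over repeated stratified random
train/test splits, keeps the best candidate, and repeats until a single
feature remains. The selected model is the global accuracy argmax over
everything evaluated, with ties resolved toward the smaller subset, then
the smaller k, then the earlier round.

Within one search, the repetition splits are derived from the master
seed only and shared across candidates, rounds and k values — a paired
design that makes candidate accuracies directly comparable and allows
per-feature squared-distance matrices to be precomputed once per split
(a candidate's distance matrix is then the parent's minus one feature's
contribution). The fast evaluator is mathematically equivalent to
scoring each candidate with :class:`~acsclass.classifiers.KNNClassifier`
on the same splits, including the deterministic tie-break rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classifiers.knn import KNNClassifier
from .dataset import Dataset, normalize
from .validation import SplitScheme, _rep_seed, make_split

DEFAULT_K_GRID = (3, 5, 7, 9, 11, 13)
DEFAULT_REPS = 100
DEFAULT_SPLIT_FRACTION = 0.7

# cap on the per-split distance-matrix cache (bytes); above it, matrices
# are recomputed per round instead of held for the whole search
_CACHE_BUDGET = 1_500_000_000


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class CandidateRecord:
    subset: tuple[int, ...]
    mean_accuracy: float


@dataclass(frozen=True)
class RoundRecord:
    """One elimination round at one k: all candidates and the argmax choice."""

    k: int
    round_index: int
    parent_subset: tuple[int, ...]
    candidates: tuple[CandidateRecord, ...]
    chosen: tuple[int, ...]
    chosen_accuracy: float


@dataclass(frozen=True)
class SelectionTrace:
    """Full record of the backward-elimination search."""

    k_grid: tuple[int, ...]
    full_set: tuple[int, ...]
    full_set_accuracy: dict[int, float]  # per k
    rounds: tuple[RoundRecord, ...]
    seed: int
    reps: int
    split_fraction: float


@dataclass(frozen=True)
class SelectionResult:
    best_subset: tuple[int, ...]
    best_k: int
    best_accuracy: float
    tie_break: str = "unique maximum"


def selection_splits(
    data: Dataset, reps: int, split_fraction: float, seed: int, stratified: bool = True
) -> list[tuple[np.ndarray, np.ndarray]]:
    """The shared (train, test) index pairs a seeded search uses."""
    scheme = SplitScheme(
        "two_way", (split_fraction, 1.0 - split_fraction), stratified, reps
    )
    return [make_split(data, scheme, _rep_seed(seed, rep, stream=2)) for rep in range(reps)]


def evaluate_subset(
    data: Dataset,
    subset: Sequence[int],
    k: int,
    reps: int = DEFAULT_REPS,
    split_fraction: float = DEFAULT_SPLIT_FRACTION,
    seed: int = 0,
    splits: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
    normalization: str = "split",
) -> float:
    """Mean k-NN test accuracy of a feature subset over repeated splits."""
    subset = tuple(subset)
    if not subset:
        raise SelectionError("empty feature subset")
    if not 0 < split_fraction < 1:
        raise SelectionError("split_fraction must lie in (0, 1)")
    if splits is None:
        splits = selection_splits(data, reps, split_fraction, seed)
    sub_data = data.select_features(subset)
    accs = []
    for train_idx, test_idx in splits:
        train_ds = sub_data.select_rows(train_idx)
        test_ds = sub_data.select_rows(test_idx)
        train_ds, test_ds = normalize(train_ds, test_ds, scope=normalization)
        if k > train_ds.n:
            raise SelectionError(f"k={k} exceeds training split size {train_ds.n}")
        model = KNNClassifier(k).fit(train_ds)
        pred = model.predict(test_ds.values)
        accs.append(float(np.mean(pred == test_ds.labels)))
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# fast shared-split evaluator


class _SplitDistances:
    """Per-split, per-feature squared-distance matrices (float32)."""

    def __init__(self, data: Dataset, splits, normalization: str):
        self.labels_train = []
        self.labels_test = []
        self._mats = []
        for train_idx, test_idx in splits:
            train_ds = data.select_rows(train_idx)
            test_ds = data.select_rows(test_idx)
            train_ds, test_ds = normalize(train_ds, test_ds, scope=normalization)
            mats = np.empty((data.p, test_ds.n, train_ds.n), dtype=np.float32)
            for j in range(data.p):
                diff = test_ds.values[:, j, None] - train_ds.values[None, :, j]
                mats[j] = (diff * diff).astype(np.float32)
            self._mats.append(mats)
            self.labels_train.append(train_ds.labels)
            self.labels_test.append(test_ds.labels)

    def feature_matrices(self, rep: int) -> np.ndarray:
        return self._mats[rep]


try:  # optional numba kernel; the numpy path below is the reference
    from numba import njit as _njit

    @_njit(cache=False)
    def _knn_batch_jit(D, k, y_train, y_test, n_classes):  # pragma: no cover
        n_cand, n_test, n_train = D.shape
        acc = np.zeros(n_cand)
        bd = np.empty(k, np.float64)
        bi = np.empty(k, np.int64)
        counts = np.empty(n_classes, np.float64)
        dsum = np.empty(n_classes, np.float64)
        for c in range(n_cand):
            correct = 0
            for t in range(n_test):
                m = 0
                for j in range(n_train):
                    d = np.float64(D[c, t, j])
                    if m < k:
                        pos = m
                        while pos > 0 and bd[pos - 1] > d:
                            bd[pos] = bd[pos - 1]
                            bi[pos] = bi[pos - 1]
                            pos -= 1
                        bd[pos] = d
                        bi[pos] = j
                        m += 1
                    elif d < bd[k - 1]:
                        pos = k - 1
                        while pos > 0 and bd[pos - 1] > d:
                            bd[pos] = bd[pos - 1]
                            bi[pos] = bi[pos - 1]
                            pos -= 1
                        bd[pos] = d
                        bi[pos] = j
                for cc in range(n_classes):
                    counts[cc] = 0.0
                    dsum[cc] = 0.0
                for i in range(k):
                    lab = y_train[bi[i]] - 1
                    counts[lab] += 1.0
                    dsum[lab] += np.sqrt(bd[i])
                best_c = -1
                best_count = -1.0
                best_md = np.inf
                for cc in range(n_classes):
                    if counts[cc] > best_count:
                        best_c = cc
                        best_count = counts[cc]
                        best_md = dsum[cc] / counts[cc] if counts[cc] > 0 else np.inf
                    elif counts[cc] == best_count and counts[cc] > 0:
                        md = dsum[cc] / counts[cc]
                        if md < best_md:
                            best_c = cc
                            best_md = md
                if best_c + 1 == y_test[t]:
                    correct += 1
            acc[c] = correct / n_test
        return acc

except ImportError:  # pragma: no cover
    _knn_batch_jit = None


def _knn_accuracy_batch(
    D: np.ndarray, k: int, y_train: np.ndarray, y_test: np.ndarray, n_classes: int
) -> np.ndarray:
    """Dispatch to the jitted kernel when available (same semantics)."""
    if _knn_batch_jit is not None:
        return _knn_batch_jit(
            np.ascontiguousarray(D), k,
            np.ascontiguousarray(y_train), np.ascontiguousarray(y_test), n_classes,
        )
    return _knn_accuracy_batch_numpy(D, k, y_train, y_test, n_classes)


def _knn_accuracy_batch_numpy(
    D: np.ndarray, k: int, y_train: np.ndarray, y_test: np.ndarray, n_classes: int
) -> np.ndarray:
    """Test accuracies for a batch of candidate distance matrices.

    ``D`` has shape (n_candidates, n_test, n_train) of squared distances.
    Neighbor selection and voting replicate KNNClassifier exactly: the k
    nearest by distance with equal distances at the boundary resolved by
    training-row order, then a plurality vote tie-broken by smaller mean
    neighbor distance and lower class index.
    """
    n_cand, n_test, n_train = D.shape
    if k >= n_train:
        raise SelectionError("k must be smaller than the training split")
    # positions 0..k-1 hold the k smallest values; position k the (k+1)-th,
    # which reveals whether ties straddle the selection boundary
    part = np.argpartition(D, (k - 1, k), axis=2)[:, :, : k + 1]
    dpart = np.take_along_axis(D, part, axis=2)
    tau = dpart[:, :, : k].max(axis=2)
    idx = part[:, :, :k]
    dk = dpart[:, :, :k]
    ambiguous = dpart[:, :, k] == tau
    if ambiguous.any():
        # boundary ties: re-select the lowest-indexed tied training rows
        ci, ti = np.nonzero(ambiguous)
        A = D[ci, ti]  # (m, n_train)
        t = tau[ci, ti][:, None]
        lt = A < t
        need = (k - lt.sum(axis=1))[:, None]
        eq = A == t
        take = lt | (eq & (np.cumsum(eq, axis=1) <= need))
        fixed = np.nonzero(take)[1].reshape(len(ci), k)  # row-major -> sorted
        idx = idx.copy()
        idx[ci, ti] = fixed
        dk = np.take_along_axis(D, idx, axis=2)
    neigh_y = y_train[idx]  # (n_cand, n_test, k)
    neigh_d = np.sqrt(dk.astype(np.float64))
    onehot = (neigh_y[..., None] == np.arange(1, n_classes + 1)).astype(np.float64)
    counts = onehot.sum(axis=2)  # (n_cand, n_test, C)
    dsums = (onehot * neigh_d[..., None]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_d = np.where(counts > 0, dsums / np.maximum(counts, 1), np.inf)
    tied = counts == counts.max(axis=2, keepdims=True)
    pred = np.argmin(np.where(tied, mean_d, np.inf), axis=2) + 1
    return (pred == y_test[None, :]).mean(axis=1)


class _FastEvaluator:
    """Scores candidate subsets over the shared splits by matrix subtraction."""

    def __init__(self, data: Dataset, splits, normalization: str):
        self.n_classes = data.schema.n_classes
        self.labels = tuple(data.schema.labels)
        self.col_of = {lab: j for j, lab in enumerate(self.labels)}
        n_train = len(splits[0][0])
        n_test = len(splits[0][1])
        est = len(splits) * len(self.labels) * n_train * n_test * 4
        if est > _CACHE_BUDGET:
            raise SelectionError(
                "distance cache would exceed the memory budget; lower reps or n"
            )
        self.dist = _SplitDistances(data, splits, normalization)
        self.reps = len(splits)

    def score_candidates(self, subsets: Sequence[tuple[int, ...]], k: int) -> np.ndarray:
        """Mean accuracy per candidate subset (shared splits, batched)."""
        cols = [np.array([self.col_of[lab] for lab in s]) for s in subsets]
        accs = np.zeros((self.reps, len(subsets)))
        for rep in range(self.reps):
            mats = self.dist.feature_matrices(rep)
            # leave-one-out structure: total minus one feature where possible
            union = sorted({c for cs in cols for c in cs})
            base = mats[union].sum(axis=0)
            D = np.empty((len(subsets), base.shape[0], base.shape[1]), dtype=np.float32)
            for i, cs in enumerate(cols):
                dropped = [c for c in union if c not in set(cs)]
                if len(dropped) <= len(cs):
                    D[i] = base
                    for c in dropped:
                        D[i] -= mats[c]
                else:
                    D[i] = mats[cs].sum(axis=0)
            accs[rep] = _knn_accuracy_batch(
                D, k, self.dist.labels_train[rep], self.dist.labels_test[rep], self.n_classes
            )
        return accs.mean(axis=0)


# ---------------------------------------------------------------------------
# search


def backward_eliminate(
    data: Dataset,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    reps: int = DEFAULT_REPS,
    split_fraction: float = DEFAULT_SPLIT_FRACTION,
    seed: int = 0,
    normalization: str = "split",
) -> SelectionTrace:
    """Greedy backward elimination over every k in the grid (full trace)."""
    if len(k_grid) == 0:
        raise SelectionError("k_grid must be non-empty")
    splits = selection_splits(data, reps, split_fraction, seed)
    evaluator = _FastEvaluator(data, splits, normalization)
    full_set = tuple(data.schema.labels)
    rounds: list[RoundRecord] = []
    full_acc: dict[int, float] = {}
    for k in k_grid:
        if k > len(splits[0][0]):
            raise SelectionError(f"k={k} exceeds the training split size")
        full_acc[k] = float(evaluator.score_candidates([full_set], k)[0])
        subset = full_set
        round_index = 0
        while len(subset) > 1:
            candidates = [tuple(f for f in subset if f != drop) for drop in subset]
            scores = evaluator.score_candidates(candidates, k)
            best_i = int(np.argmax(scores))  # ties -> drop the earlier feature
            records = tuple(
                CandidateRecord(c, float(s)) for c, s in zip(candidates, scores)
            )
            rounds.append(
                RoundRecord(
                    k, round_index, subset, records,
                    candidates[best_i], float(scores[best_i]),
                )
            )
            subset = candidates[best_i]
            round_index += 1
    return SelectionTrace(
        tuple(k_grid), full_set, full_acc, tuple(rounds), seed, reps, split_fraction
    )


def best_subset(trace: SelectionTrace) -> SelectionResult:
    """Global accuracy argmax over the trace.

    Ties prefer the smaller subset, then the smaller k, then the earlier
    round (full-set entries count as round -1).
    """
    entries: list[tuple[float, int, int, int, tuple[int, ...]]] = []
    for k in trace.k_grid:
        entries.append((trace.full_set_accuracy[k], len(trace.full_set), k, -1, trace.full_set))
    for rec in trace.rounds:
        for cand in rec.candidates:
            entries.append((cand.mean_accuracy, len(cand.subset), rec.k, rec.round_index, cand.subset))
    if not entries:
        raise SelectionError("empty trace")
    # maximize accuracy; tie-break by (size, k, round) ascending
    best = max(entries, key=lambda e: (e[0], -e[1], -e[2], -e[3]))
    ties = [e for e in entries if e[0] == best[0]]
    note = "unique maximum" if len(ties) == 1 else (
        f"{len(ties)} entries tied at {best[0]:.6f}; "
        "chose smallest subset, then smallest k, then earliest round"
    )
    return SelectionResult(best[4], best[2], best[0], note)
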