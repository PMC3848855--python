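"""Repeated random sub-sampling validation with two- and three-way splits.

Each repetition draws a fresh random partition of the rows — train/test
(two-way) or train/validation/test (three-way) — trains a classifier and
tabulates the test-set confusion matrix. Stratified splitting (default)
apportions each class across the parts by largest remainder, keeping the
rare classes represented; per-repetition seeds are derived from the
master seed through ``numpy.random.SeedSequence`` so runs are reproducible
without seed collisions.

``DEFAULT_PROTOCOL`` records the splitting mode and repetition count used
for each classifier kind in the full study protocol: learners that tune
against a validation sample (ANFIS, MLP) or are costly (RBF, bagging) use
three-way splits; the rest use two-way splits, with 50-1000 repetitions
by computational weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classifiers import ClassifierSpec, make_classifier
from .dataset import Dataset, normalize
from .metrics import ConfusionMatrix, build_cm

TWO_WAY_FRACTIONS = (0.7, 0.3)
THREE_WAY_FRACTIONS = (0.6, 0.2, 0.2)

# classifier kind -> (split mode, repetitions) in the full protocol
DEFAULT_PROTOCOL: dict[str, tuple[str, int]] = {
    "anfis": ("three_way", 50),
    "mlp": ("three_way", 100),
    "rbf": ("three_way", 1000),
    "bagging_id3": ("three_way", 1000),
    "id3": ("two_way", 1000),
    "glm": ("two_way", 1000),
    "knn": ("two_way", 1000),
    "naive_bayes": ("two_way", 1000),
}


class SplitError(ValueError):
    pass


@dataclass(frozen=True)
class SplitScheme:
    """Partitioning recipe: mode, fractions, stratification, repetitions."""

    mode: str = "two_way"
    fractions: tuple[float, ...] | None = None
    stratified: bool = True
    reps: int = 100

    def __post_init__(self) -> None:
        if self.mode not in ("two_way", "three_way"):
            raise SplitError(f"unknown split mode {self.mode!r}")
        if self.fractions is None:
            fracs = TWO_WAY_FRACTIONS if self.mode == "two_way" else THREE_WAY_FRACTIONS
            object.__setattr__(self, "fractions", fracs)
        expected = 2 if self.mode == "two_way" else 3
        if len(self.fractions) != expected:
            raise SplitError(f"{self.mode} needs {expected} fractions")
        if any(f <= 0 for f in self.fractions) or abs(sum(self.fractions) - 1.0) > 1e-9:
            raise SplitError(f"fractions {self.fractions} must be positive and sum to 1")
        if self.reps < 1:
            raise SplitError("reps must be >= 1")


def default_scheme(kind: str, reps: int | None = None, stratified: bool = True) -> SplitScheme:
    """The protocol split scheme for a classifier kind (reps overridable)."""
    mode, protocol_reps = DEFAULT_PROTOCOL[kind]
    return SplitScheme(mode=mode, reps=reps if reps is not None else protocol_reps,
                       stratified=stratified)


def largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` matching fractional ``quotas``."""
    quotas = np.asarray(quotas, dtype=float)
    alloc = np.floor(quotas).astype(int)
    short = total - alloc.sum()
    if short < 0:
        raise SplitError("quota floors exceed the total")
    order = np.argsort(-(quotas - alloc), kind="stable")
    alloc[order[:short]] += 1
    return alloc


def make_split(data: Dataset, scheme: SplitScheme, seed: int) -> tuple[np.ndarray, ...]:
    """Disjoint, exhaustive row-index parts; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    n = data.n
    fracs = np.asarray(scheme.fractions)
    part_totals = largest_remainder(n * fracs, n)
    if not scheme.stratified:
        perm = rng.permutation(n)
        bounds = np.cumsum(part_totals)[:-1]
        return tuple(np.sort(p) for p in np.split(perm, bounds))

    counts = data.class_counts()
    C = counts.size
    # per-part class allocations: largest-remainder per part, last part = rest
    remaining = counts.copy()
    allocs = []
    for k, frac in enumerate(fracs[:-1]):
        alloc = largest_remainder(frac * counts, int(part_totals[k]))
        alloc = np.minimum(alloc, remaining)
        deficit = int(part_totals[k] - alloc.sum())
        if deficit > 0:  # re-spread any clipped surplus
            room = remaining - alloc
            order = np.argsort(-room, kind="stable")
            for idx in order:
                take = min(deficit, int(room[idx]))
                alloc[idx] += take
                deficit -= take
                if deficit == 0:
                    break
        allocs.append(alloc)
        remaining = remaining - alloc
    allocs.append(remaining)
    for k, alloc in enumerate(allocs):
        if (alloc[counts > 0] < 1).any():
            cls = int(np.nonzero((alloc < 1) & (counts > 0))[0][0]) + 1
            raise SplitError(
                f"class {cls} has too few samples ({counts[cls - 1]}) to appear "
                f"in part {k} of a stratified {scheme.mode} split"
            )
    parts: list[list[int]] = [[] for _ in fracs]
    for c in range(C):
        rows = np.nonzero(data.labels == c + 1)[0]
        rows = rows[rng.permutation(rows.size)]
        start = 0
        for k in range(len(fracs)):
            take = int(allocs[k][c])
            parts[k].extend(rows[start : start + take])
            start += take
    return tuple(np.sort(np.array(p, dtype=int)) for p in parts)


@dataclass(frozen=True)
class EvalRun:
    """One repetition: its seed, test confusion matrix and tuned settings."""

    rep: int
    seed: int
    cm: ConfusionMatrix
    hyperparams: dict = field(default_factory=dict)


def _rep_seed(master_seed: int, rep: int, stream: int = 0) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(rep), int(stream)])
    return int(ss.generate_state(1)[0] % (2**31))


def repeated_evaluation(
    spec: ClassifierSpec,
    data: Dataset,
    scheme: SplitScheme,
    seed: int,
    normalization: str = "split",
    strict_protocol: bool = False,
) -> list[EvalRun]:
    """Run the repeated sub-sampling protocol for one classifier.

    Per repetition: split, min-max-normalize ratio features (fit scope per
    ``normalization``), train (passing the validation part to learners
    that use one), and tabulate the test confusion matrix.
    """
    expected_mode = DEFAULT_PROTOCOL.get(spec.kind, (scheme.mode,))[0]
    if scheme.mode != expected_mode:
        msg = (
            f"{spec.kind} is evaluated with a {expected_mode} split in the "
            f"full protocol, got {scheme.mode}"
        )
        if strict_protocol:
            raise SplitError(msg)
        warnings.warn(msg, stacklevel=2)
    runs: list[EvalRun] = []
    C = data.schema.n_classes
    for rep in range(scheme.reps):
        rs = _rep_seed(seed, rep)
        parts = make_split(data, scheme, rs)
        train_ds = data.select_rows(parts[0])
        val_ds = data.select_rows(parts[1]) if scheme.mode == "three_way" else None
        test_ds = data.select_rows(parts[-1])
        if val_ds is not None:
            train_ds, val_ds, test_ds = normalize(train_ds, val_ds, test_ds, scope=normalization)
        else:
            train_ds, test_ds = normalize(train_ds, test_ds, scope=normalization)
        model_spec = spec if spec.seed is not None else ClassifierSpec(
            spec.kind, spec.params, _rep_seed(seed, rep, stream=1)
        )
        model = make_classifier(model_spec)
        if model.requires_validation and val_ds is None:
            raise SplitError(f"{spec.kind} needs a three-way split (validation part)")
        model.fit(train_ds, val_ds)
        pred = model.predict(test_ds.values)
        runs.append(EvalRun(rep, rs, build_cm(test_ds.labels, pred, C), dict(spec.params)))
    return runs


def model_select(
    base_spec: ClassifierSpec,
    param: str,
    grid: Sequence,
    data: Dataset,
    scheme: SplitScheme,
    seed: int,
    normalization: str = "split",
) -> ClassifierSpec:
    """Grid-tune one hyperparameter by mean validation error.

    Requires a three-way scheme; every grid value is scored on the same
    repetition splits (paired comparison). The test part of each split is
    never touched. Ties go to the smaller grid value.
    """
    if scheme.mode != "three_way":
        raise SplitError("model selection requires a three-way scheme")
    if len(grid) == 0:
        raise SplitError("empty hyperparameter grid")
    grid = sorted(grid)
    errors = np.zeros(len(grid))
    for rep in range(scheme.reps):
        rs = _rep_seed(seed, rep)
        parts = make_split(data, scheme, rs)
        train_ds = data.select_rows(parts[0])
        val_ds = data.select_rows(parts[1])
        train_ds, val_ds = normalize(train_ds, val_ds, scope=normalization)
        for gi, value in enumerate(grid):
            spec = base_spec.replace_params(**{param: value})
            model_spec = spec if spec.seed is not None else ClassifierSpec(
                spec.kind, spec.params, _rep_seed(seed, rep, stream=1)
            )
            model = make_classifier(model_spec)
            model.fit(train_ds, val_ds)
            pred = model.predict(val_ds.values)
            errors[gi] += float(np.mean(pred != val_ds.labels))
    best = int(np.argmin(errors))  # argmin first-hit -> smaller value on ties
    return base_spec.replace_params(**{param: grid[best]})
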