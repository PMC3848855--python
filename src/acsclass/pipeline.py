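"""End-to-end study pipeline: generate/load -> select features -> evaluate.

``run_pipeline`` sequences the full analysis deterministically from one
master seed: obtain a dataset (from a file or the synthetic generator),
run the k-NN-wrapped backward elimination and pick the globally best
(subset, k), restrict the data to that subset, then evaluate every
classifier on its protocol split scheme and repetition count, aggregating
accuracy, APM and CPM across repetitions as mean ± standard deviation.

Repetition counts default to the full study protocol (50-1000 per
classifier kind) but are configurable; the bundled smoke profile scales
everything down for quick runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .classifiers import ClassifierSpec
from .dataset import Dataset, read_dataset
from .metrics import (
    ClassPriors,
    aggregate_runs,
    compute_apm,
    compute_cpm,
    empirical_priors,
    overall_accuracy,
)
from .schema import FeatureSchema, default_schema
from .selection import backward_eliminate, best_subset
from .synthetic import GeneratorConfig, default_acs_config, generate_dataset
from .validation import (
    DEFAULT_PROTOCOL,
    SplitScheme,
    default_scheme,
    model_select,
    repeated_evaluation,
)
from .classifiers.mlp import DEFAULT_HIDDEN_GRID

ALL_KINDS = ("glm", "knn", "naive_bayes", "id3", "bagging_id3", "mlp", "rbf", "anfis")


@dataclass(frozen=True)
class RosterEntry:
    """One classifier to evaluate, with optional hyperparameter tuning."""

    kind: str
    params: dict = field(default_factory=dict)
    reps: int | None = None  # None -> protocol default
    tune_param: str | None = None
    tune_grid: tuple | None = None
    tune_reps: int = 5


@dataclass(frozen=True)
class SelectionSettings:
    enabled: bool = True
    k_grid: tuple[int, ...] = (3, 5, 7, 9, 11, 13)
    reps: int = 100
    split_fraction: float = 0.7


@dataclass(frozen=True)
class RunConfig:
    """Complete, seedable description of one pipeline run."""

    seed: int
    generator: GeneratorConfig | None = None
    data_path: str | None = None
    schema: FeatureSchema | None = None
    selection: SelectionSettings = field(default_factory=SelectionSettings)
    roster: tuple[RosterEntry, ...] = tuple(RosterEntry(k) for k in ALL_KINDS)
    priors: str | tuple[float, ...] = "empirical"
    cpm_mode: str = "per_run"  # or "mean_apm"
    normalization: str = "split"

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.data_path is None):
            raise ValueError("exactly one of generator or data_path must be set")
        kinds = [e.kind for e in self.roster]
        if len(set(kinds)) != len(kinds):
            raise ValueError("roster kinds must be unique")
        for e in self.roster:
            if e.kind not in DEFAULT_PROTOCOL:
                raise ValueError(f"unknown classifier kind {e.kind!r}")
        if self.cpm_mode not in ("per_run", "mean_apm"):
            raise ValueError(f"unknown cpm_mode {self.cpm_mode!r}")


def default_run_config(seed: int) -> RunConfig:
    """Full-protocol run on the default synthetic registry, MLP tuned 2-13."""
    roster = tuple(
        RosterEntry(k, tune_param="n_hidden", tune_grid=DEFAULT_HIDDEN_GRID)
        if k == "mlp"
        else RosterEntry(k)
        for k in ALL_KINDS
    )
    return RunConfig(seed=seed, generator=default_acs_config(), roster=roster)


def smoke_config(seed: int, n: int = 200, reps: int = 20) -> RunConfig:
    """Scaled-down profile: small n, few repetitions, fast learners only."""
    return RunConfig(
        seed=seed,
        generator=default_acs_config(n=n),
        selection=SelectionSettings(k_grid=(3, 7), reps=10),
        roster=(
            RosterEntry("knn", reps=reps),
            RosterEntry("naive_bayes", reps=reps),
            RosterEntry("id3", reps=reps),
        ),
    )


@dataclass(frozen=True)
class ClassifierReport:
    kind: str
    params: dict
    scheme: SplitScheme
    accuracy_mean: float
    accuracy_std: float
    apm_mean: np.ndarray
    apm_std: np.ndarray
    cpm_mean: np.ndarray
    cpm_std: np.ndarray
    cm_total: int


@dataclass(frozen=True)
class RunReport:
    seed: int
    config_digest: str
    selected_features: tuple[int, ...]
    selected_k: int | None
    selection_accuracy: float | None
    class_priors: tuple[float, ...]
    classifiers: tuple[ClassifierReport, ...]


def _config_digest(config: RunConfig) -> str:
    blob = repr(config).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _obtain_dataset(config: RunConfig) -> Dataset:
    if config.generator is not None:
        ds, _ = generate_dataset(config.generator, config.seed)
        return ds
    schema = config.schema or default_schema()
    return read_dataset(Path(config.data_path).read_text(), schema)


def evaluate_roster_entry(
    entry: RosterEntry,
    data: Dataset,
    seed: int,
    normalization: str = "split",
    priors: ClassPriors | None = None,
    cpm_mode: str = "per_run",
) -> ClassifierReport:
    """Tune (optionally), run the repeated protocol, aggregate the metrics."""
    scheme = default_scheme(entry.kind, reps=entry.reps)
    spec = ClassifierSpec(entry.kind, dict(entry.params))
    if entry.tune_param is not None:
        tune_scheme = SplitScheme("three_way", reps=entry.tune_reps)
        spec = model_select(
            spec, entry.tune_param, list(entry.tune_grid), data, tune_scheme,
            seed, normalization,
        )
    runs = repeated_evaluation(spec, data, scheme, seed, normalization)
    if priors is None:
        priors = empirical_priors(data.class_counts())
    accs = [overall_accuracy(r.cm) for r in runs]
    apms = [compute_apm(r.cm).probs for r in runs]
    acc_agg = aggregate_runs([np.array([a]) for a in accs])
    apm_agg = aggregate_runs(apms)
    if cpm_mode == "per_run":
        cpms = [
            compute_cpm(compute_apm(r.cm), priors).probs for r in runs
        ]
        cpm_agg = aggregate_runs(cpms)
        cpm_mean, cpm_std = cpm_agg.mean, cpm_agg.std
    else:
        from .metrics import ProbMatrix

        cpm_mean = compute_cpm(ProbMatrix(apm_agg.mean, "APM"), priors).probs
        cpm_std = np.zeros_like(cpm_mean)
    return ClassifierReport(
        kind=entry.kind,
        params=dict(spec.params),
        scheme=scheme,
        accuracy_mean=float(acc_agg.mean[0]),
        accuracy_std=float(acc_agg.std[0]),
        apm_mean=apm_agg.mean,
        apm_std=apm_agg.std,
        cpm_mean=cpm_mean,
        cpm_std=cpm_std,
        cm_total=sum(r.cm.total for r in runs),
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full study pipeline deterministically from the master seed."""
    data = _obtain_dataset(config)
    if isinstance(config.priors, str):
        priors = empirical_priors(data.class_counts())
    else:
        priors = ClassPriors(np.asarray(config.priors))
    sel_features: tuple[int, ...]
    sel_k = sel_acc = None
    if config.selection.enabled:
        trace = backward_eliminate(
            data,
            k_grid=config.selection.k_grid,
            reps=config.selection.reps,
            split_fraction=config.selection.split_fraction,
            seed=config.seed,
            normalization=config.normalization,
        )
        result = best_subset(trace)
        sel_features, sel_k, sel_acc = result.best_subset, result.best_k, result.best_accuracy
        data = data.select_features(sel_features)
    else:
        sel_features = tuple(data.schema.labels)
    reports = tuple(
        evaluate_roster_entry(
            entry, data, config.seed, config.normalization, priors, config.cpm_mode
        )
        for entry in config.roster
    )
    return RunReport(
        seed=config.seed,
        config_digest=_config_digest(config),
        selected_features=sel_features,
        selected_k=sel_k,
        selection_accuracy=sel_acc,
        class_priors=tuple(float(p) for p in priors.probs),
        classifiers=reports,
    )


# ---------------------------------------------------------------------------
# plain-text rendering


def _matrix_block(title: str, mean: np.ndarray, std: np.ndarray, names) -> list[str]:
    lines = [title, "\t" + "\t".join(names)]
    for i, name in enumerate(names):
        cells = "\t".join(
            f"{100 * mean[i, j]:.2f} ± {100 * std[i, j]:.2f}" for j in range(len(names))
        )
        lines.append(f"{name}\t{cells}")
    return lines


def format_report(report: RunReport, class_names: Sequence[str]) -> str:
    """Human-readable tab-delimited report body (percentages, 2 decimals)."""
    lines = [
        f"seed\t{report.seed}",
        f"config\t{report.config_digest}",
        f"selected_features\t{','.join(map(str, report.selected_features))}",
        f"selected_k\t{report.selected_k}",
    ]
    if report.selection_accuracy is not None:
        lines.append(f"selection_accuracy\t{100 * report.selection_accuracy:.2f}")
    lines.append("")
    lines.append("classifier\taccuracy_mean\taccuracy_std")
    for cr in report.classifiers:
        lines.append(f"{cr.kind}\t{100 * cr.accuracy_mean:.2f}\t{100 * cr.accuracy_std:.2f}")
    for cr in report.classifiers:
        lines.append("")
        lines.extend(_matrix_block(f"APM ({cr.kind})", cr.apm_mean, cr.apm_std, class_names))
        lines.extend(_matrix_block(f"CPM ({cr.kind})", cr.cpm_mean, cr.cpm_std, class_names))
    # diagonal summaries (bar-chart data): per-class accuracy / correctness
    lines.append("")
    lines.append("diagonals\t" + "\t".join(class_names))
    for cr in report.classifiers:
        apm_d = "\t".join(f"{100 * v:.2f}" for v in np.diag(cr.apm_mean))
        cpm_d = "\t".join(f"{100 * v:.2f}" for v in np.diag(cr.cpm_mean))
        lines.append(f"APM_diag {cr.kind}\t{apm_d}")
        lines.append(f"CPM_diag {cr.kind}\t{cpm_d}")
    return "\n".join(lines) + "\n"
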