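"""Wrapper-based gene selection: GBPSO driven by SVM cross-validation accuracy.

A filtered gene panel defines the bit-mask search space. The fitness of
a mask is the mean stratified K-fold cross-validation accuracy of an SVM
(polynomial kernel by default) trained on the masked genes. The swarm
search is repeated once per fold repetition (10 by default); a gene
enters a branch's final subset only if it appears in at least
``min_repeat`` (default 7) of the repetitions' best masks, and the three
filter branches' finals are merged by set union.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .filters import FILTER_NAMES, RankedGeneList, filter_stage
from .gbpso import SwarmConfig, SwarmResult, run_gbpso
from .io import ExpressionMatrix, GeneList, HoldoutSplit, split_holdout
from .reduction import ReductionReport, reduce_dataset

__all__ = [
    "FitnessConfig",
    "PipelineConfig",
    "SelectionResult",
    "PipelineResult",
    "stage_seed",
    "make_svm",
    "svm_cv_fitness",
    "select_repeatable",
    "gbpso_branch",
    "merge_subsets",
    "run_pipeline",
]

_KERNEL_ALIASES = {"polynomial": "poly", "poly": "poly", "linear": "linear", "rbf": "rbf"}


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive an independent, reproducible sub-seed (< 2^31) for a stage."""
    digest = hashlib.blake2s(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class FitnessConfig:
    """SVM and cross-validation settings for the wrapper fitness."""

    kernel: str = "polynomial"
    degree: int = 3
    C: float = 1.0
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in _KERNEL_ALIASES:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.C <= 0:
            raise ValueError("regularization strength C must be positive")


def make_svm(config: FitnessConfig) -> SVC:
    return SVC(
        kernel=_KERNEL_ALIASES[config.kernel],
        degree=config.degree,
        C=config.C,
        gamma="scale",
    )


def _cv_folds(y: np.ndarray, n_folds: int, seed: int):
    labels, counts = np.unique(y, return_counts=True)
    if len(labels) < 2:
        raise ValueError("both classes are required for cross-validation")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} observations; "
            f"cannot form {n_folds} stratified folds with both classes"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _masked_cv_accuracy(
    X: np.ndarray, y: np.ndarray, mask: np.ndarray, folds, config: FitnessConfig
) -> float:
    if not mask.any():
        return 0.0
    Xm = X[:, mask]
    accs = []
    for train_idx, test_idx in folds:
        clf = make_svm(config)
        clf.fit(Xm[train_idx], y[train_idx])
        accs.append(float(np.mean(clf.predict(Xm[test_idx]) == y[test_idx])))
    return float(np.mean(accs))


def svm_cv_fitness(
    matrix: ExpressionMatrix, mask: np.ndarray, config: FitnessConfig
) -> float:
    """Mean stratified CV accuracy of the SVM on the masked genes.

    The empty mask scores 0, so it can never be an optimum.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (matrix.n_genes,):
        raise ValueError("mask length must equal the gene count")
    folds = _cv_folds(np.asarray(matrix.labels), config.cv_folds, config.seed)
    return _masked_cv_accuracy(matrix.values, np.asarray(matrix.labels), mask, folds, config)


def select_repeatable(counts: dict[str, int], threshold: int) -> GeneList:
    """Genes appearing in at least ``threshold`` runs, ordered by count
    (descending) then identifier. Raising the threshold never enlarges
    the result."""
    ids = sorted((g for g, c in counts.items() if c >= threshold), key=lambda g: (-counts[g], g))
    return GeneList(ids, np.asarray([counts[g] for g in ids], dtype=float))


@dataclass
class SelectionResult:
    """Outcome of the repeated GBPSO-SVM runs on one filter branch."""

    panel: GeneList
    per_run_subsets: list[GeneList]
    frequencies: dict[str, int]
    threshold: int
    final: GeneList
    per_run_fitness: list[float]
    traces: list[list[float]] = field(default_factory=list, repr=False)

    @property
    def n_runs(self) -> int:
        return len(self.per_run_subsets)


def gbpso_branch(
    train: ExpressionMatrix,
    panel: RankedGeneList,
    fitness_config: FitnessConfig,
    swarm_config: SwarmConfig,
    K: int = 10,
    threshold: int = 7,
) -> SelectionResult:
    """Run GBPSO-SVM ``K`` times over ``panel`` and keep repeatable genes.

    Run *k* evaluates fitness with its own stratified fold structure and
    swarm seed (both derived from the configs' seeds). A deterministic
    full-panel particle is injected into each initial swarm so the
    returned best subset is never worse than the whole panel. Genes
    appearing in at least ``threshold`` of the K best masks form the
    final subset, ordered by frequency (descending) then identifier.
    """
    if threshold > K:
        warnings.warn(
            f"repeatability threshold {threshold} exceeds the {K} runs; "
            "the final subset will be empty",
            stacklevel=2,
        )
    sub = train.subset_genes(panel.ids)
    X, y = sub.values, np.asarray(sub.labels)
    D = sub.n_genes

    per_run_subsets: list[GeneList] = []
    per_run_fitness: list[float] = []
    traces: list[list[float]] = []
    counts: dict[str, int] = {g: 0 for g in panel.ids}
    for k in range(K):
        folds = _cv_folds(y, fitness_config.cv_folds, stage_seed(fitness_config.seed, f"cv{k}"))
        cache: dict[bytes, float] = {}

        def fitness(mask: np.ndarray) -> float:
            key = np.packbits(mask).tobytes()
            if key not in cache:
                cache[key] = _masked_cv_accuracy(X, y, mask, folds, fitness_config)
            return cache[key]

        cfg = replace(swarm_config, seed=stage_seed(swarm_config.seed, f"swarm{k}"))
        result: SwarmResult = run_gbpso(
            D, fitness, cfg, initial_positions=[np.ones(D, dtype=bool)]
        )
        chosen = [g for g, bit in zip(panel.ids, result.best_position) if bit]
        for g in chosen:
            counts[g] += 1
        per_run_subsets.append(GeneList(chosen))
        per_run_fitness.append(result.best_fitness)
        traces.append(result.trace)

    final = select_repeatable(counts, threshold)
    return SelectionResult(
        panel=panel,
        per_run_subsets=per_run_subsets,
        frequencies=counts,
        threshold=threshold,
        final=final,
        per_run_fitness=per_run_fitness,
        traces=traces,
    )


def merge_subsets(subsets: Sequence[GeneList]) -> GeneList:
    """Set union of branch subsets, ordered by total branch frequency
    (gene-list scores, where present) then identifier."""
    if not subsets:
        raise ValueError("need at least one subset to merge")
    total: dict[str, float] = {}
    for lst in subsets:
        scores = lst.scores if lst.scores is not None else np.ones(len(lst))
        for g, s in zip(lst.ids, scores):
            total[g] = total.get(g, 0.0) + float(s)
    order = sorted(total, key=lambda g: (-total[g], g))
    return GeneList(order, np.asarray([total[g] for g in order]))


# ----------------------------------------------------------------------
# Full pipeline


@dataclass
class PipelineConfig:
    """End-to-end configuration; one master seed derives all stage seeds."""

    train_fraction: float = 0.85
    reduction_threshold: float = 0.95
    variance_cutoff: float = 0.15
    filters: tuple[str, ...] = FILTER_NAMES
    panel_size: int = 200
    filter_folds: int = 10
    n_repeats: int = 10
    min_repeat: int = 7
    swarm: SwarmConfig = field(default_factory=SwarmConfig)
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        unknown = set(f.lower() for f in self.filters) - set(FILTER_NAMES)
        if unknown:
            raise ValueError(f"unknown filters: {sorted(unknown)}")
        if self.panel_size < 1 or self.filter_folds < 1:
            raise ValueError("panel_size and filter_folds must be >= 1")
        if self.n_repeats < 1 or self.min_repeat < 1:
            raise ValueError("n_repeats and min_repeat must be >= 1")


@dataclass
class PipelineResult:
    config: PipelineConfig
    split: HoldoutSplit
    reduced: ExpressionMatrix
    reduction_report: ReductionReport
    panels: dict[str, RankedGeneList]
    branches: dict[str, SelectionResult]
    merged: GeneList
    cv_accuracy: float | None
    holdout_accuracy: float | None
    baseline_holdout_accuracy: float | None


def run_pipeline(matrix: ExpressionMatrix, config: PipelineConfig) -> PipelineResult:
    """Execute holdout split → reduction → filter branches → GBPSO-SVM →
    merge → evaluation, deterministically from ``config.seed``."""
    from .evaluation import evaluate, holdout_evaluate

    split = split_holdout(matrix, config.train_fraction, stage_seed(config.seed, "split"))
    reduced, report = reduce_dataset(
        split.train, config.reduction_threshold, config.variance_cutoff
    )
    panel_size = min(config.panel_size, reduced.n_genes)

    panels: dict[str, RankedGeneList] = {}
    branches: dict[str, SelectionResult] = {}
    for name in config.filters:
        name = name.lower()
        panels[name] = filter_stage(
            reduced,
            name,
            R=panel_size,
            K=config.filter_folds,
            seed=stage_seed(config.seed, f"filter:{name}"),
        )
        fitness_cfg = replace(config.fitness, seed=stage_seed(config.seed, f"fitness:{name}"))
        swarm_cfg = replace(config.swarm, seed=stage_seed(config.seed, f"swarm:{name}"))
        branches[name] = gbpso_branch(
            reduced,
            panels[name],
            fitness_cfg,
            swarm_cfg,
            K=config.n_repeats,
            threshold=config.min_repeat,
        )
    merged = merge_subsets([branches[n].final for n in branches if len(branches[n].final)] or
                           [GeneList([])])

    cv_acc = holdout_acc = None
    if len(merged):
        cv_acc = evaluate(
            split.train,
            merged,
            folds=config.fitness.cv_folds,
            seed=stage_seed(config.seed, "eval"),
            classifier=make_svm(config.fitness),
        ).cv_accuracy
        holdout_acc = holdout_evaluate(
            split.train, split.holdout, merged, classifier=make_svm(config.fitness)
        )
    baseline = holdout_evaluate(
        split.train,
        split.holdout,
        GeneList(list(matrix.gene_ids)),
        classifier=make_svm(config.fitness),
    )
    return PipelineResult(
        config=config,
        split=split,
        reduced=reduced,
        reduction_report=report,
        panels=panels,
        branches=branches,
        merged=merged,
        cv_accuracy=cv_acc,
        holdout_accuracy=holdout_acc,
        baseline_holdout_accuracy=baseline,
    )
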