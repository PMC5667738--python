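"""Statistical filter ranking of genes and rank aggregation across folds.

Three univariate two-class filters are provided:

* ``tt``  — Welch two-sample t statistic t = (c1 − c2)/√(σ1²/n + σ2²/m),
  with Welch–Satterthwaite degrees of freedom; genes are ranked by
  ascending p-value.
* ``cor`` — correlation-with-class score
  S(f) = Σ_k P_k (c_k − c)² / (σ²(f) Σ_k P_k (1 − P_k)), K = 2; ranked
  descending.
* ``wrs`` — Wilcoxon rank-sum pair count
  s(g) = #{(i ∈ class0, j ∈ class1) : x_j(g) − x_i(g) ≤ 0} (ties count),
  folded into q(g) = max(s(g), N0·N1 − s(g)); ranked descending by q.

A filter is run once per cross-validation fold (scoring on the K−1
training folds), each fold contributes a top-R list, and the lists are
fused with Borda-style position weights w_i(f) = R − position + 1 summed
over folds (the global weight w(f)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

from .io import ExpressionMatrix, GeneList

__all__ = [
    "FilterScores",
    "RankedGeneList",
    "FILTER_NAMES",
    "welch_scores",
    "cor_scores",
    "wrs_scores",
    "rank_genes",
    "aggregate_fold_ranks",
    "filter_stage",
    "overlap_percent",
]

FILTER_NAMES = ("tt", "cor", "wrs")

#: Ordered gene list whose scores are aggregated fold weights.
RankedGeneList = GeneList


@dataclass
class FilterScores:
    """Per-gene filter statistics; only the fields of the filter that
    produced the object are populated."""

    gene_ids: np.ndarray
    t: np.ndarray | None = None
    p: np.ndarray | None = None
    df: np.ndarray | None = None
    cor: np.ndarray | None = None
    wrs_s: np.ndarray | None = None
    wrs_q: np.ndarray | None = None
    flags: dict = field(default_factory=dict)


def _class_split(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    matrix.require_two_classes()
    idx = matrix.class_indices()
    c0, c1 = (idx[c] for c in matrix.classes)
    return matrix.values[c0], matrix.values[c1]


def welch_scores(matrix: ExpressionMatrix) -> FilterScores:
    """Welch t and two-sided p per gene (class variances not pooled)."""
    x0, x1 = _class_split(matrix)
    n, m = len(x0), len(x1)
    if n < 2 or m < 2:
        raise ValueError("Welch test needs >= 2 observations per class")
    c1, c2 = x0.mean(axis=0), x1.mean(axis=0)
    v1, v2 = x0.var(axis=0, ddof=1), x1.var(axis=0, ddof=1)
    se2 = v1 / n + v2 / m
    diff = c1 - c2
    degenerate = se2 == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, diff / np.sqrt(np.where(degenerate, 1.0, se2)))
        df = np.where(
            degenerate,
            1.0,
            se2**2
            / np.where(
                degenerate,
                1.0,
                (v1 / n) ** 2 / (n - 1) + (v2 / m) ** 2 / (m - 1),
            ),
        )
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    # zero variance in both classes: equal means -> no evidence (p = 1);
    # unequal means -> perfectly separated, flagged and ranked first
    flags = {}
    if degenerate.any():
        sep = degenerate & (diff != 0)
        p[degenerate & ~sep] = 1.0
        p[sep] = np.finfo(float).tiny
        t[degenerate] = 0.0
        if sep.any():
            flags["zero_variance_separated"] = list(matrix.gene_ids[sep])
    return FilterScores(gene_ids=matrix.gene_ids.copy(), t=t, p=p, df=df, flags=flags)


def cor_scores(matrix: ExpressionMatrix) -> FilterScores:
    """Correlation-with-class S(f) per gene (zero-variance genes score 0)."""
    x0, x1 = _class_split(matrix)
    n, m = len(x0), len(x1)
    total = n + m
    p0, p1 = n / total, m / total
    c = matrix.values.mean(axis=0)
    c0, c1 = x0.mean(axis=0), x1.mean(axis=0)
    var_f = matrix.values.var(axis=0, ddof=1)
    numer = p0 * (c0 - c) ** 2 + p1 * (c1 - c) ** 2
    denom_weight = p0 * (1 - p0) + p1 * (1 - p1)
    zero_var = var_f == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(zero_var, 0.0, numer / (np.where(zero_var, 1.0, var_f) * denom_weight))
    flags = {}
    if zero_var.any():
        flags["zero_variance"] = list(matrix.gene_ids[zero_var])
    return FilterScores(gene_ids=matrix.gene_ids.copy(), cor=s, flags=flags)


def wrs_scores(matrix: ExpressionMatrix) -> FilterScores:
    """Cross-class pair counts s(g) and folded importance q(g) per gene."""
    x0, x1 = _class_split(matrix)
    n0, n1 = len(x0), len(x1)
    n_genes = matrix.n_genes
    s = np.empty(n_genes, dtype=float)
    sorted0 = np.sort(x0, axis=0)
    for j in range(n_genes):
        # pairs with x_j(case) - x_i(control) <= 0, i.e. x0_i >= x1_j
        below = np.searchsorted(sorted0[:, j], x1[:, j], side="left")
        s[j] = float(n0 * n1 - below.sum())
    q = np.maximum(s, n0 * n1 - s)
    return FilterScores(gene_ids=matrix.gene_ids.copy(), wrs_s=s, wrs_q=q)


def _order(gene_ids, key: np.ndarray, ascending: bool) -> list[int]:
    sign = 1.0 if ascending else -1.0
    return sorted(range(len(gene_ids)), key=lambda j: (sign * key[j], gene_ids[j]))


def rank_genes(scores: FilterScores, method: str) -> RankedGeneList:
    """Order genes by a filter's criterion with lexicographic tie-break."""
    method = method.lower()
    if method == "tt":
        order = _order(scores.gene_ids, scores.p, ascending=True)
        key = scores.p
    elif method == "cor":
        order = _order(scores.gene_ids, scores.cor, ascending=False)
        key = scores.cor
    elif method == "wrs":
        order = _order(scores.gene_ids, scores.wrs_q, ascending=False)
        key = scores.wrs_q
    else:
        raise ValueError(f"unknown filter {method!r}; expected one of {FILTER_NAMES}")
    return RankedGeneList(
        [scores.gene_ids[j] for j in order], np.asarray([key[j] for j in order])
    )


def _score_and_rank(matrix: ExpressionMatrix, method: str) -> RankedGeneList:
    method = method.lower()
    if method == "tt":
        return rank_genes(welch_scores(matrix), "tt")
    if method == "cor":
        return rank_genes(cor_scores(matrix), "cor")
    if method == "wrs":
        return rank_genes(wrs_scores(matrix), "wrs")
    raise ValueError(f"unknown filter {method!r}; expected one of {FILTER_NAMES}")


def aggregate_fold_ranks(per_fold_lists) -> RankedGeneList:
    """Fuse equally long per-fold rankings by summed position weights.

    The gene at position 1 of a fold's list of length R receives weight
    R, position 2 receives R − 1, …, position R receives 1; a gene
    absent from a fold contributes 0 there. Genes are returned in
    descending total weight with lexicographic tie-break; genes absent
    from every list are excluded.
    """
    lists = [list(lst) for lst in per_fold_lists]
    if not lists:
        raise ValueError("need at least one fold list")
    r = len(lists[0])
    if any(len(lst) != r for lst in lists):
        raise ValueError("fold lists must have equal length")
    weights: dict[str, float] = {}
    for lst in lists:
        if len(set(lst)) != len(lst):
            raise ValueError("duplicate gene within a fold list")
        for pos, gene in enumerate(lst, start=1):
            weights[gene] = weights.get(gene, 0.0) + (r - pos + 1)
    order = sorted(weights, key=lambda g: (-weights[g], g))
    return RankedGeneList(order, np.asarray([weights[g] for g in order]))


def filter_stage(
    train: ExpressionMatrix,
    filter: str,
    R: int = 200,
    K: int = 10,
    seed: int = 0,
) -> RankedGeneList:
    """Top-R panel from K stratified-fold filter runs on the training set.

    Each fold run scores genes on the K−1 training folds and keeps its
    top R; the K lists are fused with :func:`aggregate_fold_ranks` and
    the leading R genes of the fused ranking are returned. With K = 1
    this degenerates to a single full-train ranking.
    """
    if R > train.n_genes:
        raise ValueError(f"R={R} exceeds the {train.n_genes} available genes")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        full = _score_and_rank(train, filter)
        return RankedGeneList(full.ids[:R], full.scores[:R])
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    fold_lists = []
    y = np.asarray(train.labels)
    for train_idx, _ in skf.split(np.zeros(train.n_obs), y):
        ranked = _score_and_rank(train.subset_obs(np.sort(train_idx)), filter)
        fold_lists.append(ranked.ids[:R])
    fused = aggregate_fold_ranks(fold_lists)
    top = fused.ids[:R]
    return RankedGeneList(top, fused.scores[: len(top)])


def overlap_percent(a: GeneList, b: GeneList) -> float:
    """Percentage of genes shared by two equally long lists."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("gene lists must be non-empty")
    if len(a) != len(b):
        raise ValueError("gene lists must have equal length")
    return 100.0 * len(a.as_set() & b.as_set()) / len(a)
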