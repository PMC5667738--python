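"""Pre-selection: remove genes expressed near-identically in both classes.

Genes are screened with a variance-conditioned ratio rule. Per class the
coefficient of variation (CV = SD/mean) decides which location statistic
is trustworthy: a high-variance gene (CV above the cutoff in either
class, default 0.15) is compared between classes by its *median* ratio,
a low-variance gene by its *mean* ratio. A gene whose ratio falls inside
the symmetric band [t, 1/t] (default t = 0.95) is considered equally
expressed in cases and controls and removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneList

__all__ = [
    "MEAN_RATIO",
    "MEDIAN_RATIO",
    "GeneClassStats",
    "ReductionReport",
    "compute_gene_class_stats",
    "variance_partition",
    "ratio_in_band",
    "reduce_dataset",
]

MEAN_RATIO = "mean_ratio"
MEDIAN_RATIO = "median_ratio"


@dataclass
class GeneClassStats:
    """Per-gene, per-class location and dispersion summaries.

    Arrays are shaped (n_genes,); class 0 / class 1 follow the sorted
    label order of the source matrix. CV is NaN where the class mean is
    not positive (which forces the median branch).
    """

    gene_ids: np.ndarray
    mean0: np.ndarray
    mean1: np.ndarray
    median0: np.ndarray
    median1: np.ndarray
    var0: np.ndarray
    var1: np.ndarray
    cv0: np.ndarray
    cv1: np.ndarray


@dataclass
class ReductionReport:
    threshold: float
    variance_cutoff: float
    removed: GeneList
    kept: GeneList
    branch: dict[str, str]  # gene -> MEAN_RATIO | MEDIAN_RATIO
    ratio: dict[str, float]  # gene -> class0/class1 branch-statistic ratio
    flagged_nonpositive: list[str]

    def to_frame(self) -> pd.DataFrame:
        removed = self.removed.as_set()
        genes = list(self.branch)
        return pd.DataFrame(
            {
                "gene_id": genes,
                "branch": [self.branch[g] for g in genes],
                "ratio": [self.ratio[g] for g in genes],
                "removed": [g in removed for g in genes],
            }
        )


def compute_gene_class_stats(matrix: ExpressionMatrix) -> GeneClassStats:
    matrix.require_two_classes()
    idx = matrix.class_indices()
    c0, c1 = (idx[c] for c in matrix.classes)
    if len(c0) < 2 or len(c1) < 2:
        raise ValueError("each class needs >= 2 observations for gene statistics")
    x0, x1 = matrix.values[c0], matrix.values[c1]

    def _cv(x: np.ndarray) -> np.ndarray:
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean > 0, sd / mean, np.nan)
        return cv

    return GeneClassStats(
        gene_ids=matrix.gene_ids.copy(),
        mean0=x0.mean(axis=0),
        mean1=x1.mean(axis=0),
        median0=np.median(x0, axis=0),
        median1=np.median(x1, axis=0),
        var0=x0.var(axis=0, ddof=1),
        var1=x1.var(axis=0, ddof=1),
        cv0=_cv(x0),
        cv1=_cv(x1),
    )


def variance_partition(
    stats: GeneClassStats, variance_cutoff: float = 0.15
) -> np.ndarray:
    """Assign each gene to the mean-ratio or median-ratio branch.

    A gene takes the median branch iff its CV strictly exceeds the
    cutoff in *either* class (or its CV is undefined because a class
    mean is non-positive); a CV exactly at the cutoff stays on the mean
    branch.
    """
    high0 = np.isnan(stats.cv0) | (stats.cv0 > variance_cutoff)
    high1 = np.isnan(stats.cv1) | (stats.cv1 > variance_cutoff)
    return np.where(high0 | high1, MEDIAN_RATIO, MEAN_RATIO)


def ratio_in_band(
    class0_stat: float, class1_stat: float, threshold: float = 0.95
) -> bool:
    """True iff class0_stat/class1_stat lies in [threshold, 1/threshold].

    Non-positive statistics never fall in the band (the gene is kept and
    flagged by the caller). Symmetric under swapping the two classes.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if class0_stat <= 0 or class1_stat <= 0:
        return False
    ratio = class0_stat / class1_stat
    return threshold <= ratio <= 1.0 / threshold


def reduce_dataset(
    matrix: ExpressionMatrix,
    threshold: float = 0.95,
    variance_cutoff: float = 0.15,
) -> tuple[ExpressionMatrix, ReductionReport]:
    """Drop genes whose branch-statistic ratio is inside the similarity band.

    Observation order and the relative order of surviving genes are
    preserved. Raises if no gene survives.
    """
    stats = compute_gene_class_stats(matrix)
    branches = variance_partition(stats, variance_cutoff)

    branch_map: dict[str, str] = {}
    ratio_map: dict[str, float] = {}
    flagged: list[str] = []
    keep_mask = np.ones(matrix.n_genes, dtype=bool)
    for j, gene in enumerate(matrix.gene_ids):
        if branches[j] == MEDIAN_RATIO:
            s0, s1 = stats.median0[j], stats.median1[j]
        else:
            s0, s1 = stats.mean0[j], stats.mean1[j]
        branch_map[gene] = str(branches[j])
        ratio_map[gene] = s0 / s1 if s1 > 0 else np.nan
        if s0 <= 0 or s1 <= 0:
            flagged.append(gene)
            continue
        if ratio_in_band(s0, s1, threshold):
            keep_mask[j] = False

    kept_ids = [g for g, k in zip(matrix.gene_ids, keep_mask) if k]
    removed_ids = [g for g, k in zip(matrix.gene_ids, keep_mask) if not k]
    if not kept_ids:
        raise ValueError("no genes survive reduction")
    report = ReductionReport(
        threshold=threshold,
        variance_cutoff=variance_cutoff,
        removed=GeneList(removed_ids),
        kept=GeneList(kept_ids),
        branch=branch_map,
        ratio=ratio_map,
        flagged_nonpositive=flagged,
    )
    return matrix.subset_genes(kept_ids), report
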