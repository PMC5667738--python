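"""Synthetic two-class expression matrices with planted discriminative genes.

The generator emulates the statistical structure of case/control
microarray intensity data with heavy within-class variance: log-normal
baseline expression, multiplicative outlier spikes that pull the mean
away from the median, inflated variance in the case class, and a planted
minority of genes whose case-class mean is shifted by a stated number of
within-class standard deviations. The planted list is returned so that
selection stages can be scored for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, GeneList

__all__ = ["SyntheticSpec", "generate", "recovery_score"]


@dataclass
class SyntheticSpec:
    """Study-design parameters for the synthetic generator.

    Attributes
    ----------
    n_class0, n_class1 : int
        Observations per class (control, case). Defaults mirror a cohort
        of ~70 individuals per group.
    n_genes : int
        Total genes; defaults to tens of thousands as on a whole-genome
        expression array.
    n_discriminative : int
        Planted genes whose case-class mean is shifted; a small minority.
    effect_size : float
        Case-vs-control mean shift in units of the control within-class
        standard deviation; direction random per gene.
    base_mean : float
        Baseline expression level (arbitrary intensity units).
    base_cv : float
        Baseline within-class coefficient of variation (SD/mean).
    outlier_rate : float
        Per-cell probability of a multiplicative outlier spike.
    outlier_scale : float
        Multiplier applied to outlier cells (≥ 1).
    case_variance_inflation : float
        Factor (≥ 1) by which the case-class variance exceeds control.
    seed : int
        Generator seed; identical specs produce bit-identical matrices.
    """

    n_class0: int = 70
    n_class1: int = 70
    n_genes: int = 20_000
    n_discriminative: int = 200
    effect_size: float = 2.0
    base_mean: float = 100.0
    base_cv: float = 0.4
    outlier_rate: float = 0.02
    outlier_scale: float = 5.0
    case_variance_inflation: float = 1.5
    seed: int = 0
    class0_label: str = field(default="control", repr=False)
    class1_label: str = field(default="case", repr=False)

    def validate(self) -> None:
        if min(self.n_class0, self.n_class1, self.n_genes) < 1:
            raise ValueError("all counts must be positive")
        if not 0 <= self.n_discriminative <= self.n_genes:
            raise ValueError("n_discriminative must lie in [0, n_genes]")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must lie in [0, 1]")
        if self.outlier_scale < 1.0:
            raise ValueError("outlier_scale must be >= 1")
        if self.case_variance_inflation < 1.0:
            raise ValueError("case_variance_inflation must be >= 1")
        if self.base_mean <= 0 or self.base_cv <= 0:
            raise ValueError("base_mean and base_cv must be positive")


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    # parameterized so the arithmetic mean is `mean` and SD is `cv * mean`
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GeneList]:
    """Draw a labelled matrix and the list of planted gene identifiers."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n0, n1, g = spec.n_class0, spec.n_class1, spec.n_genes

    control = _lognormal(rng, spec.base_mean, spec.base_cv, (n0, g))
    case_cv = spec.base_cv * np.sqrt(spec.case_variance_inflation)
    case = _lognormal(rng, spec.base_mean, case_cv, (n1, g))

    planted_idx = rng.choice(g, size=spec.n_discriminative, replace=False)
    planted_idx.sort()
    if spec.n_discriminative:
        # additive shift of the case class only, ± effect × control SD
        direction = rng.choice([-1.0, 1.0], size=spec.n_discriminative)
        shift = direction * spec.effect_size * spec.base_cv * spec.base_mean
        case[:, planted_idx] += shift

    values = np.vstack([control, case])
    if spec.outlier_rate > 0:
        spikes = rng.random(values.shape) < spec.outlier_rate
        values = np.where(spikes, values * spec.outlier_scale, values)

    gene_ids = np.array([f"g{i:05d}" for i in range(g)], dtype=object)
    obs_ids = np.array(
        [f"ctrl{i:03d}" for i in range(n0)] + [f"case{i:03d}" for i in range(n1)],
        dtype=object,
    )
    labels = np.array([spec.class0_label] * n0 + [spec.class1_label] * n1, dtype=object)
    matrix = ExpressionMatrix(values, gene_ids, obs_ids, labels)
    planted = GeneList([gene_ids[i] for i in planted_idx])
    return matrix, planted


def recovery_score(selected: GeneList, planted: GeneList) -> float:
    """Fraction of planted genes present in ``selected`` (in [0, 1])."""
    if len(planted) == 0:
        raise ValueError("planted gene list is empty")
    return len(selected.as_set() & planted.as_set()) / len(planted)
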