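"""Accuracy harness: cross-validated and holdout evaluation of gene panels.

Any object honouring the scikit-learn ``fit(X, y)`` / ``predict(X)``
contract can be evaluated; the polynomial-kernel SVM used by the wrapper
stage is the default. Accuracies are reported as percentages (full
precision retained; round at display time).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone

from .filters import filter_stage
from .io import ExpressionMatrix, GeneList
from .reduction import reduce_dataset
from .wrapper import FitnessConfig, _cv_folds, make_svm

__all__ = ["EvaluationRow", "evaluate", "holdout_evaluate", "threshold_sweep"]


@dataclass
class EvaluationRow:
    """One (gene panel × classifier) evaluation record."""

    cv_accuracy: float  # mean of fold accuracies, percent
    fold_accuracies: list[float]  # percent
    n_genes: int
    folds: int
    seed: int


def _fresh(classifier):
    if isinstance(classifier, BaseEstimator):
        return clone(classifier)
    return copy.deepcopy(classifier)


def _default_classifier():
    return make_svm(FitnessConfig())


def evaluate(
    train: ExpressionMatrix,
    panel: GeneList,
    classifier=None,
    folds: int = 10,
    seed: int = 0,
) -> EvaluationRow:
    """Stratified K-fold CV accuracy (%) of a classifier on a gene panel."""
    if len(panel) == 0:
        raise ValueError("gene panel is empty")
    classifier = classifier if classifier is not None else _default_classifier()
    sub = train.subset_genes(panel.ids)
    y = np.asarray(sub.labels)
    fold_accs = []
    for train_idx, test_idx in _cv_folds(y, folds, seed):
        clf = _fresh(classifier)
        clf.fit(sub.values[train_idx], y[train_idx])
        acc = float(np.mean(clf.predict(sub.values[test_idx]) == y[test_idx]))
        fold_accs.append(100.0 * acc)
    return EvaluationRow(
        cv_accuracy=float(np.mean(fold_accs)),
        fold_accuracies=fold_accs,
        n_genes=len(panel),
        folds=folds,
        seed=seed,
    )


def holdout_evaluate(
    train: ExpressionMatrix,
    holdout: ExpressionMatrix,
    panel: GeneList,
    classifier=None,
) -> float:
    """Accuracy (%) on a held-out set of a classifier fit once on ``train``.

    The holdout plays the role of a new, never-involved dataset: it
    takes no part in selection or model fitting.
    """
    if len(panel) == 0:
        raise ValueError("gene panel is empty")
    classifier = classifier if classifier is not None else _default_classifier()
    sub_train = train.subset_genes(panel.ids)
    sub_hold = holdout.subset_genes(panel.ids)
    clf = _fresh(classifier)
    clf.fit(sub_train.values, np.asarray(sub_train.labels))
    pred = clf.predict(sub_hold.values)
    return 100.0 * float(np.mean(pred == np.asarray(sub_hold.labels)))


def threshold_sweep(
    matrix: ExpressionMatrix,
    thresholds,
    filter: str = "tt",
    R: int = 200,
    classifier=None,
    folds: int = 10,
    filter_folds: int = 10,
    seed: int = 0,
    variance_cutoff: float = 0.15,
) -> pd.DataFrame:
    """CV accuracy of the filtered panel at several reduction thresholds.

    For each similarity threshold the matrix is reduced, the filter's
    top-R panel is built and evaluated; rows report (threshold,
    surviving genes, cv accuracy %).
    """
    rows = []
    for t in thresholds:
        if not 0.0 < t < 1.0:
            raise ValueError("thresholds must lie in (0, 1)")
        reduced, _ = reduce_dataset(matrix, t, variance_cutoff)
        panel = filter_stage(
            reduced, filter, R=min(R, reduced.n_genes), K=filter_folds, seed=seed
        )
        row = evaluate(reduced, panel, classifier=classifier, folds=folds, seed=seed)
        rows.append(
            {
                "threshold": t,
                "n_genes_kept": reduced.n_genes,
                "panel_size": len(panel),
                "cv_accuracy": row.cv_accuracy,
            }
        )
    return pd.DataFrame(rows)
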