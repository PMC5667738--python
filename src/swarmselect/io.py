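"""Labelled expression-matrix containers and CSV I/O.

The on-disk dialect is a plain CSV with observations as rows, genes as
columns and a single label column (default ``class``) holding the
two-class phenotype (e.g. ``control`` / ``case``). Transposed files
(genes as rows) are handled by an orientation flag at read time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneList",
    "HoldoutSplit",
    "read_expression_csv",
    "write_expression_csv",
    "read_gene_list",
    "write_gene_list",
    "split_holdout",
]

DEFAULT_LABEL_COLUMN = "class"


class SingleClassWarning(UserWarning):
    """Raised as a warning when a loaded matrix contains one class only."""


@dataclass
class ExpressionMatrix:
    """Observations × genes expression table with a binary class label.

    Parameters
    ----------
    values : ndarray, shape (n_obs, n_genes)
        Finite expression values; missing values are an error, never imputed.
    gene_ids : sequence of str
        Unique, non-empty column identifiers.
    obs_ids : sequence of str
        Unique row identifiers.
    labels : sequence of str
        Class label per observation (two distinct values for any
        statistical operation).
    """

    values: np.ndarray
    gene_ids: np.ndarray
    obs_ids: np.ndarray
    labels: np.ndarray
    single_class: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.obs_ids = np.asarray(self.obs_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (observations × genes)")
        n_obs, n_genes = self.values.shape
        if len(self.obs_ids) != n_obs:
            raise ValueError("obs_ids length does not match number of rows")
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match number of columns")
        if len(self.labels) != n_obs:
            raise ValueError("one label per observation is required")
        if any(g is None or str(g) == "" for g in self.gene_ids):
            raise ValueError("gene identifiers must be non-empty")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene identifiers")
        if len(set(self.obs_ids)) != n_obs:
            raise ValueError("duplicate observation identifiers")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"missing value at ({self.obs_ids[i]},{self.gene_ids[j]})"
            )
        self.single_class = len(set(self.labels)) < 2

    # ------------------------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        """Distinct class labels as (class0, class1).

        ``control`` (when present) is always class0, the reference
        class; otherwise labels are taken in sorted order.
        """
        labs = sorted(set(self.labels))
        if "control" in labs:
            labs.remove("control")
            labs.insert(0, "control")
        return labs

    def class_indices(self) -> dict[str, np.ndarray]:
        return {c: np.flatnonzero(self.labels == c) for c in self.classes}

    def require_two_classes(self) -> None:
        if self.single_class:
            raise ValueError("both classes must be present for this operation")

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to the given genes, in the given order."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            cols = [pos[g] for g in gene_ids]
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not present in matrix") from None
        return ExpressionMatrix(
            self.values[:, cols],
            np.asarray(list(gene_ids), dtype=object),
            self.obs_ids.copy(),
            self.labels.copy(),
        )

    def subset_obs(self, idx: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[idx], self.gene_ids.copy(), self.obs_ids[idx], self.labels[idx]
        )

    def to_frame(self, label_column: str = DEFAULT_LABEL_COLUMN) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.obs_ids, columns=self.gene_ids)
        df.insert(0, label_column, self.labels)
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.values, other.values, rtol=0, atol=0)
            and list(self.gene_ids) == list(other.gene_ids)
            and list(self.obs_ids) == list(other.obs_ids)
            and list(self.labels) == list(other.labels)
        )


@dataclass
class GeneList:
    """Ordered, duplicate-free list of gene identifiers with optional scores."""

    ids: list[str]
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = [str(g) for g in self.ids]
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate gene identifiers in gene list")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if len(self.scores) != len(self.ids):
                raise ValueError("one score per gene is required")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[str]:
        return iter(self.ids)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.ids)

    def as_set(self) -> set[str]:
        return set(self.ids)


@dataclass
class HoldoutSplit:
    """Stratified train / holdout partition of an expression matrix."""

    train: ExpressionMatrix
    holdout: ExpressionMatrix
    seed: int


# ----------------------------------------------------------------------
# CSV round trip


def read_expression_csv(
    path,
    orientation: str = "obs_rows",
    label_column: str = DEFAULT_LABEL_COLUMN,
) -> ExpressionMatrix:
    """Read a labelled expression CSV.

    ``orientation='gene_rows'`` transposes on load: genes are file rows,
    observations are columns, and the label row is named ``label_column``.
    """
    if orientation not in ("obs_rows", "gene_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "gene_rows":
        # mixed label/value columns: keep raw strings, convert after transpose
        df = pd.read_csv(path, index_col=0, dtype=str).T
    else:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    labels = df[label_column].astype(str).to_numpy()
    data = df.drop(columns=[label_column])
    if data.shape[1] == 0:
        raise ValueError("file contains no gene columns")
    numeric = data.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~data.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at ({data.index[i]},{data.columns[j]})"
        )
    missing = numeric.isna()
    if missing.to_numpy().any():
        i, j = np.argwhere(missing.to_numpy())[0]
        raise ValueError(f"missing value at ({data.index[i]},{data.columns[j]})")
    matrix = ExpressionMatrix(
        data.astype(float).to_numpy(dtype=float),  # astype is round-trip exact
        numeric.columns.to_numpy(dtype=object),
        data.index.astype(str).to_numpy(dtype=object),
        labels,
    )
    if matrix.single_class:
        warnings.warn(
            f"{path}: only one class present; statistical operations will fail",
            SingleClassWarning,
            stacklevel=2,
        )
    return matrix


def write_expression_csv(
    matrix: ExpressionMatrix,
    path,
    label_column: str = DEFAULT_LABEL_COLUMN,
) -> None:
    """Write ``matrix`` so that :func:`read_expression_csv` recovers it.

    Values are written with 17 significant digits (exact float64 round trip).
    """
    if matrix.n_genes == 0:
        raise ValueError("refusing to write a matrix with no genes")
    matrix.to_frame(label_column).to_csv(path, float_format="%.17g", index_label="obs_id")


def read_gene_list(path) -> GeneList:
    """Read a one-identifier-per-line gene list."""
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    return GeneList(ids)


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# ----------------------------------------------------------------------
# Holdout split


def split_holdout(
    matrix: ExpressionMatrix, train_fraction: float, seed: int = 0
) -> HoldoutSplit:
    """Stratified train / holdout split.

    Per class, ``floor(train_fraction * n_class)`` observations go to the
    training part; the rest form the held-out ("non-involved") part that
    selection never sees. Deterministic given ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    matrix.require_two_classes()
    rng = np.random.default_rng(seed)
    by_class = matrix.class_indices()
    targets = {c: train_fraction * len(idx) for c, idx in by_class.items()}
    counts = {c: int(np.floor(t)) for c, t in targets.items()}
    # total train size is the floor of the summed per-class targets;
    # leftover seats go to the classes with the largest remainders
    leftover = int(np.floor(sum(targets.values()))) - sum(counts.values())
    for c in sorted(by_class, key=lambda c: (counts[c] - targets[c], c))[:leftover]:
        counts[c] += 1
    train_idx: list[int] = []
    hold_idx: list[int] = []
    for cls, idx in by_class.items():
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} needs at least 2 observations")
        n_train = counts[cls]
        if n_train == 0 or n_train == len(idx):
            raise ValueError(
                f"train_fraction {train_fraction} leaves class {cls!r} empty "
                "in one part"
            )
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train])
        hold_idx.extend(perm[n_train:])
    train_idx_arr = np.sort(np.asarray(train_idx))
    hold_idx_arr = np.sort(np.asarray(hold_idx))
    return HoldoutSplit(
        matrix.subset_obs(train_idx_arr), matrix.subset_obs(hold_idx_arr), seed
    )
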