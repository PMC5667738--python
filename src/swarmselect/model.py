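"""Model/Results facade over the hybrid filter + GBPSO-SVM pipeline.

`GeneSelectionModel` is constructed from a labelled expression matrix
(or a DataFrame with a class column) plus the pipeline configuration;
``fit()`` executes the full selection pipeline and returns a
`GeneSelectionResults` carrying the merged gene subset, per-branch
diagnostics and accuracy estimates, with a ``summary()`` table.
"""

from __future__ import annotations

import pandas as pd

from .io import DEFAULT_LABEL_COLUMN, ExpressionMatrix, GeneList
from .wrapper import PipelineConfig, PipelineResult, run_pipeline

__all__ = ["GeneSelectionModel", "GeneSelectionResults"]


class GeneSelectionModel:
    """Hybrid filter/wrapper gene-selection model for two-class data.

    Parameters
    ----------
    data : ExpressionMatrix
        Labelled observations × genes matrix.
    config : PipelineConfig, optional
        Stage parameters; keyword overrides (e.g. ``panel_size=200``)
        are applied on top of the defaults.
    """

    def __init__(self, data: ExpressionMatrix, config: PipelineConfig | None = None, **overrides):
        data.require_two_classes()
        self.data = data
        if config is None:
            config = PipelineConfig(**overrides)
        elif overrides:
            from dataclasses import replace

            config = replace(config, **overrides)
        self.config = config

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_column: str = DEFAULT_LABEL_COLUMN,
        **overrides,
    ) -> "GeneSelectionModel":
        """Build from a DataFrame with one label column, genes as the rest."""
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not in DataFrame")
        labels = df[label_column].astype(str).to_numpy()
        values = df.drop(columns=[label_column])
        matrix = ExpressionMatrix(
            values.to_numpy(dtype=float),
            values.columns.to_numpy(dtype=object),
            df.index.astype(str).to_numpy(dtype=object),
            labels,
        )
        return cls(matrix, **overrides)

    def fit(self, seed: int | None = None) -> "GeneSelectionResults":
        """Run the full pipeline; ``seed`` overrides the config's seed."""
        config = self.config
        if seed is not None:
            from dataclasses import replace

            config = replace(config, seed=seed)
        return GeneSelectionResults(self, run_pipeline(self.data, config))


class GeneSelectionResults:
    """Fitted selection results with accuracy diagnostics."""

    def __init__(self, model: GeneSelectionModel, pipeline: PipelineResult):
        self.model = model
        self.pipeline = pipeline

    # -- primary estimates ------------------------------------------------
    @property
    def merged_genes(self) -> GeneList:
        """The union of the three branch subsets (the selected panel)."""
        return self.pipeline.merged

    @property
    def branch_genes(self) -> dict[str, GeneList]:
        return {name: br.final for name, br in self.pipeline.branches.items()}

    @property
    def gene_frequencies(self) -> pd.DataFrame:
        rows = [
            {"filter": name, "gene_id": g, "count": c, "selected": c >= br.threshold}
            for name, br in self.pipeline.branches.items()
            for g, c in sorted(br.frequencies.items())
        ]
        return pd.DataFrame(rows)

    @property
    def cv_accuracy(self) -> float | None:
        """Merged-panel CV accuracy (%) on the training part."""
        return self.pipeline.cv_accuracy

    @property
    def holdout_accuracy(self) -> float | None:
        """Merged-panel accuracy (%) on the non-involved holdout."""
        return self.pipeline.holdout_accuracy

    @property
    def baseline_holdout_accuracy(self) -> float | None:
        """All-genes SVM accuracy (%) on the holdout, for comparison."""
        return self.pipeline.baseline_holdout_accuracy

    # -- display ----------------------------------------------------------
    def summary(self) -> str:
        p = self.pipeline
        cfg = p.config
        lines = [
            "Hybrid filter + GBPSO-SVM gene selection",
            "=" * 46,
            f"observations (train/holdout): {p.split.train.n_obs}/{p.split.holdout.n_obs}",
            f"genes in, after reduction:    {p.split.train.n_genes}, {p.reduced.n_genes}",
            f"reduction band:               [{cfg.reduction_threshold:g}, "
            f"{1 / cfg.reduction_threshold:.4g}]  (CV cutoff {cfg.variance_cutoff:g})",
            f"panel size / repeats / min:   {cfg.panel_size} / {cfg.n_repeats} / {cfg.min_repeat}",
            "-" * 46,
        ]
        for name, br in p.branches.items():
            lines.append(
                f"branch {name.upper():<4} final subset: {len(br.final):>4} genes "
                f"(best run fitness {max(br.per_run_fitness):.3f})"
            )
        lines.append(f"merged subset:            {len(p.merged):>4} genes")
        if p.cv_accuracy is not None:
            lines.append(f"merged CV accuracy:         {p.cv_accuracy:.1f}%")
        if p.holdout_accuracy is not None:
            lines.append(f"merged holdout accuracy:    {p.holdout_accuracy:.1f}%")
        if p.baseline_holdout_accuracy is not None:
            lines.append(f"all-genes holdout accuracy: {p.baseline_holdout_accuracy:.1f}%")
        lines.append(f"seed: {cfg.seed}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<GeneSelectionResults: {len(self.merged_genes)} merged genes>"
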