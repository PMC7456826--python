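"""Core data containers shared by the pipeline stages.

All containers wrap labeled pandas objects and validate their own
consistency on construction, so downstream code can assume aligned,
rectangular, fully labeled matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Gene-level RNA-seq counts for a two-condition design.

    Attributes
    ----------
    counts : pd.DataFrame
        Genes x samples, non-negative integers, indexed by gene id.
    gene_lengths : pd.Series
        Transcript length in bases per gene, strictly positive,
        indexed like ``counts``.
    condition : pd.Series
        Condition label per sample, indexed by sample id matching the
        columns of ``counts``.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    condition: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.gene_lengths.index):
            raise ValueError("gene_lengths index must match counts index")
        if not self.counts.columns.equals(self.condition.index):
            raise ValueError("condition index must match counts columns")
        if (self.gene_lengths <= 0).any():
            bad = self.gene_lengths.index[self.gene_lengths <= 0][0]
            raise ValueError(f"non-positive gene length for gene {bad!r}")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def condition_levels(self) -> list[str]:
        """The distinct condition labels, in order of first appearance."""
        return list(dict.fromkeys(self.condition))


@dataclass
class ExpressionMatrix:
    """log2(FPKM + pseudocount) expression, genes x samples."""

    values: pd.DataFrame
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if not np.isfinite(np.asarray(self.values, dtype=float)).all():
            raise ValueError("expression values must be finite")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class PanelData:
    """Cell-line panel: log-expression and drug-response AUC%, columns aligned.

    ``expr`` is genes x cell lines (log2 RPKM-like units); ``auc`` is
    drugs x cell lines on a 0-100 AUC% scale where lower means more
    sensitive. Columns are identical and identically ordered.
    """

    expr: pd.DataFrame
    auc: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.expr.columns.equals(self.auc.columns):
            raise ValueError("expr and auc cell-line columns must be aligned")
        if self.expr.columns.has_duplicates:
            raise ValueError("duplicated cell-line ids")

    @property
    def cell_line_ids(self) -> pd.Index:
        return self.expr.columns

    @property
    def n_lines(self) -> int:
        return self.expr.shape[1]
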