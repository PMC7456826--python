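"""FPKM normalization, log2 transform, and PCA variance summaries.

FPKM_gs = 1e9 * count_gs / (length_g * librarysize_s), with the library
size defined as the column sum of the count matrix. Expression used for
differential testing is log2(FPKM + pseudocount), pseudocount 1 by
default so FPKM 0 maps to 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from tkiscreen.datatypes import CountMatrix, ExpressionMatrix


def fpkm(counts: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments."""
    lib = counts.counts.sum(axis=0)
    zero = lib.index[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample {zero[0]!r}")
    lengths = counts.gene_lengths.to_numpy(dtype=float)[:, None]
    vals = 1e9 * counts.counts.to_numpy(dtype=float) / (lengths * lib.to_numpy()[None, :])
    return pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids)


def log_transform(fpkm_matrix: pd.DataFrame, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(FPKM + pseudocount); monotone in FPKM."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (fpkm_matrix.to_numpy() < 0).any():
        raise ValueError("FPKM values must be non-negative")
    return ExpressionMatrix(
        values=np.log2(fpkm_matrix + pseudocount), pseudocount=pseudocount
    )


def pca_variance_explained(expr: ExpressionMatrix) -> np.ndarray:
    """Proportion of variance per principal component, samples as observations.

    Genes are centered by their mean across samples before the
    decomposition; no gene-level standardization is applied. Proportions
    are non-negative, sorted non-increasing and sum to 1. A constant
    matrix yields all-zero proportions rather than an error.
    """
    x = expr.values.to_numpy(dtype=float).T  # samples x genes
    if x.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    x = x - x.mean(axis=0, keepdims=True)
    s = np.linalg.svd(x, compute_uv=False)
    var = s**2
    total = var.sum()
    if total == 0:
        return np.zeros(min(x.shape))
    return var / total
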