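"""Moderated-t differential expression with BH FDR and a three-part DEG filter.

The model is the standard empirical-Bayes variance shrinkage used for
small-replicate microarray/RNA-seq designs: per-gene residual variances
s_g^2 on df degrees of freedom are assumed drawn from a scaled
inverse-chi-square prior with hyperparameters (d0, s0^2), estimated by a
method-of-moments fit on log s^2. The posterior variance

    s_tilde_g^2 = (d0 * s0^2 + df * s_g^2) / (d0 + df)

replaces s_g^2 in the two-sample t statistic, which then has d0 + df
degrees of freedom. With d0 = 0 the statistic reduces to the ordinary
pooled-variance t; d0 = inf means complete shrinkage to s0^2.

A gene is called differentially expressed when fdr < 0.05, |log2FC| > 1
and mean FPKM across all samples > 1 (all strict, all configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from tkiscreen.datatypes import CountMatrix, ExpressionMatrix
from tkiscreen import normalize


@dataclass
class ModerationParams:
    """Hyperparameters of the scaled inverse-chi-square variance prior."""

    d0: float  # prior degrees of freedom, may be inf
    s0_sq: float  # prior variance, log2-expression units squared

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("d0 must be positive")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


def gene_stats(expr: ExpressionMatrix, condition: pd.Series) -> pd.DataFrame:
    """Per-gene means, log2 fold change, pooled variance and residual df.

    log2fc is mean(condition 2) - mean(condition 1), conditions taken in
    order of first appearance in ``condition``. Each condition needs at
    least two samples for the pooled variance to exist.
    """
    levels = list(dict.fromkeys(condition))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {levels}")
    g1 = condition.index[condition == levels[0]]
    g2 = condition.index[condition == levels[1]]
    n1, n2 = len(g1), len(g2)
    if min(n1, n2) < 2:
        raise ValueError("each condition needs >= 2 samples (variance undefined)")
    x1 = expr.values[g1].to_numpy(dtype=float)
    x2 = expr.values[g2].to_numpy(dtype=float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    out = pd.DataFrame(
        {
            "mean1": m1,
            "mean2": m2,
            "log2fc": m2 - m1,
            "s2": s2,
            "df": n1 + n2 - 2,
            "n1": n1,
            "n2": n2,
        },
        index=expr.gene_ids,
    )
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_moderation(s2: np.ndarray, df: float) -> ModerationParams:
    """Method-of-moments fit of the (d0, s0^2) variance prior from log s^2.

    Under the model, e_g = log s_g^2 - digamma(df/2) + log(df/2) has mean
    log s0^2 + digamma(d0/2) - log(d0/2) and variance trigamma(df/2) +
    trigamma(d0/2); the excess of var(e) over trigamma(df/2) identifies
    d0, and the mean then identifies s0^2. When the empirical spread does
    not exceed its sampling-theory expectation, d0 = inf and s0^2 is the
    (geometric-mean-based) common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 10:
        raise ValueError("need >= 10 genes with positive variance")
    if np.ptp(s2) == 0:
        # degenerate: all variances identical -> point-mass prior at that value
        return ModerationParams(d0=np.inf, s0_sq=float(s2[0]))
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        half_d0 = _trigamma_inverse(float(evar))
        d0 = 2.0 * half_d0
        s0_sq = np.exp(emean + special.digamma(half_d0) - np.log(half_d0))
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return ModerationParams(d0=float(d0), s0_sq=float(s0_sq))


def posterior_s2(s2: np.ndarray, df: float, params: ModerationParams) -> np.ndarray:
    """Shrunken variance: convex combination of prior and observed."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(params.d0):
        return np.full_like(s2, params.s0_sq)
    return (params.d0 * params.s0_sq + df * s2) / (params.d0 + df)


def moderated_t(
    gene_table: pd.DataFrame, params: ModerationParams | None
) -> pd.DataFrame:
    """Moderated (or, with ``params=None``, ordinary pooled) t and p per gene.

    t = log2fc / sqrt(s_tilde^2 * (1/n1 + 1/n2)) on d0 + df degrees of
    freedom. A gene with zero posterior variance and nonzero log2fc is
    degenerate: p is reported as 0 and flagged.
    """
    df = float(gene_table["df"].iloc[0])
    n1 = gene_table["n1"].to_numpy(dtype=float)
    n2 = gene_table["n2"].to_numpy(dtype=float)
    s2 = gene_table["s2"].to_numpy(dtype=float)
    lfc = gene_table["log2fc"].to_numpy(dtype=float)
    if params is None:
        s2_post = s2
        df_total = df
    else:
        s2_post = posterior_s2(s2, df, params)
        df_total = params.d0 + df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    degenerate = (se == 0) & (lfc != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where((se == 0) & (lfc == 0), 1.0, p)
    p = np.where(degenerate, 0.0, p)
    t_stat = t.copy()
    t_stat[degenerate] = np.sign(lfc[degenerate]) * np.inf
    out = gene_table.copy()
    out["t_stat"] = t_stat
    out["p_raw"] = p
    out["degenerate"] = degenerate
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    table: pd.DataFrame,
    fdr_cut: float = 0.05,
    lfc_cut: float = 1.0,
    expr_cut: float = 1.0,
) -> pd.DataFrame:
    """Apply the three-part DEG filter with strict inequalities.

    Requires columns fdr, log2fc, mean_fpkm. Adds ``direction`` (up/down
    by sign of log2fc) and ``is_deg``; a gene is a DEG iff fdr < fdr_cut,
    |log2fc| > lfc_cut and mean_fpkm > expr_cut.
    """
    out = table.copy()
    out["direction"] = np.where(out["log2fc"] >= 0, "up", "down")
    out["is_deg"] = (
        (out["fdr"] < fdr_cut)
        & (out["log2fc"].abs() > lfc_cut)
        & (out["mean_fpkm"] > expr_cut)
    )
    return out


def deg_counts(table: pd.DataFrame) -> dict[str, int]:
    """n_up, n_down, n_total among called DEGs."""
    deg = table[table["is_deg"]]
    n_up = int((deg["direction"] == "up").sum())
    n_down = int((deg["direction"] == "down").sum())
    return {"n_up": n_up, "n_down": n_down, "n_total": n_up + n_down}


def run_de(
    counts: CountMatrix,
    pseudocount: float = 1.0,
    moderation: bool = True,
    fdr_cut: float = 0.05,
    lfc_cut: float = 1.0,
    expr_cut: float = 1.0,
) -> pd.DataFrame:
    """Counts -> full DEG table: FPKM, log2 transform, moderated t, BH, filter."""
    fpkm_mat = normalize.fpkm(counts)
    expr = normalize.log_transform(fpkm_mat, pseudocount=pseudocount)
    table = gene_stats(expr, counts.condition)
    params = (
        estimate_moderation(table["s2"].to_numpy(), float(table["df"].iloc[0]))
        if moderation
        else None
    )
    table = moderated_t(table, params)
    table["fdr"] = bh_adjust(table["p_raw"].to_numpy())
    table["mean_fpkm"] = fpkm_mat.mean(axis=1)
    return call_degs(table, fdr_cut=fdr_cut, lfc_cut=lfc_cut, expr_cut=expr_cut)
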