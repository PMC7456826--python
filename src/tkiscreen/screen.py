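"""Expression x drug-response correlation screen over a cell-line panel.

Upregulated DEGs with at least one annotated drug are correlated
(Pearson by default) with each drug's AUC% across the cell lines shared
by the expression and response matrices. A (gene, drug) pair is a hit
when r < -0.3 and p < 0.001, both strict: higher expression of the gene
predicting a lower AUC, i.e. better response. Drugs are ranked by their
number of distinct hit genes and kept when that count reaches
``min_genes`` (default 4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tkiscreen.datatypes import PanelData

logger = logging.getLogger(__name__)

R_CUT = -0.3
P_CUT = 1e-3
MIN_GENES = 4


def intersect_panel(expr: pd.DataFrame, auc: pd.DataFrame) -> PanelData:
    """Restrict both matrices to their shared cell lines, identically ordered."""
    common = expr.columns.intersection(auc.columns)
    if len(common) == 0:
        raise ValueError("no shared cell lines between expression and AUC matrices")
    logger.info(
        "panel intersection: %d expression x %d response -> %d shared cell lines",
        expr.shape[1], auc.shape[1], len(common),
    )
    return PanelData(expr=expr[common], auc=auc[common])


def select_candidates(deg_table: pd.DataFrame, drug_targets: pd.DataFrame) -> list[str]:
    """Upregulated DEGs that have at least one annotated drug, sorted by id."""
    up = deg_table.index[deg_table["is_deg"] & (deg_table["direction"] == "up")]
    annotated = set(drug_targets["gene_id"])
    return sorted(g for g in up if g in annotated)


def correlate_pair(
    expr: np.ndarray, auc: np.ndarray, method: str = "pearson"
) -> tuple[int, float, float]:
    """Correlation between one gene's expression and one drug's AUC.

    Pairs with a missing entry are dropped. p comes from the exact-null
    t transform t = r*sqrt((n-2)/(1-r^2)) on n-2 df, two-sided; |r| = 1
    gives p = 0. Returns (n_used, r, p); with fewer than 3 complete
    pairs or zero variance in either vector, r and p are NaN.
    """
    expr = np.asarray(expr, dtype=float)
    auc = np.asarray(auc, dtype=float)
    ok = ~(np.isnan(expr) | np.isnan(auc))
    x, y = expr[ok], auc[ok]
    n = int(ok.sum())
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return n, np.nan, np.nan
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return n, r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return n, r, p


def run_screen(
    candidates: list[str],
    panel: PanelData,
    r_cut: float = R_CUT,
    p_cut: float = P_CUT,
    method: str = "pearson",
) -> pd.DataFrame:
    """Evaluate every (candidate gene, drug) pair; flag hits.

    The full table is retained, not only hits. Candidate genes missing
    from the panel expression matrix are skipped with a warning. The
    expected number of null false positives (n_pairs * p_cut) is logged
    for transparency since no multiplicity correction is applied.
    """
    present = [g for g in candidates if g in panel.expr.index]
    missing = sorted(set(candidates) - set(present))
    if missing:
        logger.warning("candidate genes absent from panel, skipped: %s", missing)
    n_pairs = len(present) * panel.auc.shape[0]
    logger.info(
        "screening %d gene x drug pairs; expected null false positives ~ %.2f",
        n_pairs, n_pairs * p_cut,
    )
    rows = []
    for g in present:
        ev = panel.expr.loc[g].to_numpy()
        for d in panel.auc.index:
            n, r, p = correlate_pair(ev, panel.auc.loc[d].to_numpy(), method=method)
            hit = bool(np.isfinite(r) and np.isfinite(p) and r < r_cut and p < p_cut)
            rows.append((g, d, n, r, p, hit))
    return pd.DataFrame(
        rows, columns=["gene_id", "drug_id", "n_used", "r", "p", "hit"]
    )


def rank_drugs(
    pairs: pd.DataFrame, min_genes: int = MIN_GENES
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-drug hit-gene counts and the genes x drugs boolean hit matrix.

    A drug is kept when it has at least ``min_genes`` distinct hit genes.
    The ranking is sorted by hit count descending, ties broken by drug id
    ascending.
    """
    hit_matrix = (
        pairs.pivot(index="gene_id", columns="drug_id", values="hit")
        .fillna(False)
        .astype(bool)
    )
    rows = []
    for drug, grp in pairs.groupby("drug_id", sort=True):
        hit_genes = sorted(grp.loc[grp["hit"], "gene_id"].unique())
        rows.append((drug, ",".join(hit_genes), len(hit_genes), len(hit_genes) >= min_genes))
    ranking = pd.DataFrame(rows, columns=["drug_id", "hit_genes", "n_hits", "kept"])
    ranking = ranking.sort_values(
        ["n_hits", "drug_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return ranking, hit_matrix
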