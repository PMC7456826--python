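"""End-to-end orchestration with a reproducible run manifest.

Stages run in order normalize -> deg -> enrich -> screen (each
toggleable); the manifest records input checksums, thresholds, package
version and per-stage row counts, which together with the inputs and
seed suffice to reproduce a run exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

import tkiscreen
from tkiscreen import diffexpr, enrichment, io, normalize, screen

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and stage toggles for a full pipeline run.

    Threshold defaults are the study's operating point: DEGs at
    FDR < 0.05, |log2FC| > 1, mean FPKM > 1; screen hits at r < -0.3,
    p < 0.001; drugs kept with >= 4 hit genes.
    """

    counts: str = ""
    conditions: str = ""
    gene_sets: str = ""
    drug_targets: str = ""
    panel_expr: str = ""
    panel_auc: str = ""
    outdir: str = "results"
    fdr_cut: float = 0.05
    lfc_cut: float = 1.0
    expr_cut: float = 1.0
    r_cut: float = -0.3
    p_cut: float = 1e-3
    min_genes: int = 4
    pseudocount: float = 1.0
    moderation: bool = True
    seed: int = 0
    run_normalize: bool = True
    run_deg: bool = True
    run_enrich: bool = True
    run_screen: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    outdir = io.ensure_dir(config.outdir)
    manifest: dict = {
        "version": tkiscreen.__version__,
        "config": asdict(config),
        "inputs": {},
        "stages": {},
    }
    for key in ("counts", "conditions", "gene_sets", "drug_targets",
                "panel_expr", "panel_auc"):
        path = getattr(config, key)
        if path:
            if not Path(path).is_file():
                raise FileNotFoundError(f"input file for {key!r} not found: {path}")
            manifest["inputs"][key] = {"path": path, "sha256": _sha256(path)}

    deg_table = None
    try:
        cm = io.read_counts(config.counts, config.conditions)

        if config.run_normalize:
            stage = "normalize"
            fpkm_mat = normalize.fpkm(cm)
            expr = normalize.log_transform(fpkm_mat, config.pseudocount)
            io.write_matrix(fpkm_mat, outdir / "fpkm.tsv", "gene_id")
            io.write_matrix(expr.values, outdir / "log2_fpkm.tsv", "gene_id")
            pcs = normalize.pca_variance_explained(expr)
            manifest["stages"]["normalize"] = {
                "n_genes": int(fpkm_mat.shape[0]),
                "n_samples": int(fpkm_mat.shape[1]),
                "pc1_variance_fraction": float(pcs[0]),
            }

        if config.run_deg:
            stage = "deg"
            deg_table = diffexpr.run_de(
                cm,
                pseudocount=config.pseudocount,
                moderation=config.moderation,
                fdr_cut=config.fdr_cut,
                lfc_cut=config.lfc_cut,
                expr_cut=config.expr_cut,
            )
            io.write_table(deg_table, outdir / "deg_full.tsv", index=True,
                           index_label="gene_id")
            io.write_table(deg_table[deg_table["is_deg"]],
                           outdir / "deg_filtered.tsv", index=True,
                           index_label="gene_id")
            manifest["stages"]["deg"] = diffexpr.deg_counts(deg_table)

        if config.run_enrich:
            stage = "enrich"
            if deg_table is None:
                raise ValueError("enrich stage requires the deg stage")
            sets = enrichment.read_gmt(config.gene_sets)
            universe = list(
                deg_table.index[deg_table["mean_fpkm"] > config.expr_cut]
            )
            query = [g for g in deg_table.index[deg_table["is_deg"]]
                     if g in set(universe)]
            enr = enrichment.ora(query, universe, sets, fdr_cut=config.fdr_cut)
            io.write_table(enr, outdir / "enrichment.tsv")
            manifest["stages"]["enrich"] = {
                "n_sets": int(len(enr)),
                "n_significant": int(enr["significant"].sum()),
            }

        if config.run_screen:
            stage = "screen"
            if deg_table is None:
                raise ValueError("screen stage requires the deg stage")
            targets = io.read_table(config.drug_targets)
            expr_panel = io.read_matrix(config.panel_expr, "gene_id")
            auc_panel = io.read_matrix(config.panel_auc, "drug_id")
            panel = screen.intersect_panel(expr_panel, auc_panel)
            candidates = screen.select_candidates(deg_table, targets)
            pairs = screen.run_screen(
                candidates, panel, r_cut=config.r_cut, p_cut=config.p_cut
            )
            ranking, hit_matrix = screen.rank_drugs(pairs, min_genes=config.min_genes)
            io.write_table(pairs, outdir / "screen_pairs.tsv")
            io.write_table(ranking, outdir / "drug_ranking.tsv")
            io.write_matrix(hit_matrix.astype(int), outdir / "hit_matrix.tsv",
                            "gene_id")
            manifest["stages"]["screen"] = {
                "n_candidates": len(candidates),
                "n_cell_lines": panel.n_lines,
                "n_pairs": int(len(pairs)),
                "n_hits": int(pairs["hit"].sum()),
                "n_drugs_kept": int(ranking["kept"].sum()),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
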