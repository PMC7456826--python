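"""Readers and writers for the pipeline's plain-text table dialects.

Counts travel as a TSV with columns gene_id, length, then one column per
sample, paired with a sample-to-condition TSV. Expression, AUC and hit
matrices are plain indexed TSVs; dose-response tables are CSVs with
columns dose, replicate, viability.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from tkiscreen.datatypes import CountMatrix


def write_counts(cm: CountMatrix, counts_path, condition_path) -> None:
    out = cm.counts.copy()
    out.insert(0, "length", cm.gene_lengths)
    out.to_csv(counts_path, sep="\t", index_label="gene_id")
    cm.condition.rename("condition").to_csv(
        condition_path, sep="\t", index_label="sample_id"
    )


def read_counts(counts_path, condition_path) -> CountMatrix:
    table = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    if "length" not in table.columns:
        raise ValueError(f"{counts_path}: missing required 'length' column")
    lengths = table["length"]
    counts = table.drop(columns="length")
    cond = pd.read_csv(condition_path, sep="\t", index_col="sample_id")["condition"]
    missing = [s for s in counts.columns if s not in cond.index]
    if missing:
        raise ValueError(f"{condition_path}: samples without condition: {missing}")
    return CountMatrix(
        counts=counts, gene_lengths=lengths, condition=cond.loc[counts.columns]
    )


def write_matrix(mat: pd.DataFrame, path, index_label: str) -> None:
    mat.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path, index_label: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_label)


def write_table(table: pd.DataFrame, path, index: bool = False, index_label=None) -> None:
    table.to_csv(path, sep="\t", index=index, index_label=index_label)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_dose_response(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_dose_response(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"dose", "viability"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return table


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
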