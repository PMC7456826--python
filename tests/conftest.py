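import numpy as np
import pandas as pd
import pytest

from tkiscreen import normalize, simulate
from tkiscreen.datatypes import CountMatrix


@pytest.fixture(scope="session")
def small_counts():
    """2000-gene, 3v3 count matrix with 5% up / 5% down planted at lfc 2.5."""
    return simulate.gen_two_condition_counts(
        2000, 3, frac_up=0.05, frac_down=0.05, lfc=2.5, seed=11
    )


@pytest.fixture(scope="session")
def small_expr(small_counts):
    cm, _ = small_counts
    return normalize.log_transform(normalize.fpkm(cm)), cm.condition


@pytest.fixture
def toy_counts():
    """Hand-sized count matrix for exact FPKM arithmetic."""
    genes = pd.Index(["g1", "g2", "g3"], name="gene_id")
    samples = pd.Index(["s1", "s2", "s3", "s4"], name="sample_id")
    counts = pd.DataFrame(
        [[100, 10, 0, 5], [400, 40, 10, 5], [999500, 999950, 999990, 999990]],
        index=genes, columns=samples,
    )
    return CountMatrix(
        counts=counts,
        gene_lengths=pd.Series([1000, 2000, 500], index=genes, name="length"),
        condition=pd.Series(["A", "A", "C", "C"], index=samples, name="condition"),
    )


@pytest.fixture(scope="session")
def strong_panel():
    """144-line panel with one drug coupled to six genes at coupling -5."""
    genes = [f"G{i:05d}" for i in range(10)]
    drugs = [f"D{i:03d}" for i in range(5)]
    planted = simulate.PanelSimTruth(
        pairs=[(genes[i], drugs[0], -5.0) for i in range(6)], noise_sd=1.0
    )
    panel, truth = simulate.gen_panel(144, genes, drugs, planted, seed=3)
    return panel, truth, genes, drugs
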