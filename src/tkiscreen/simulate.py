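"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: negative-binomial
RNA-seq counts with planted fold changes, a cell-line panel with planted
linear gene-drug couplings, 4PL dose-response viability tables, gene-set
collections, and gene-to-drug annotation tables. All generators take an
explicit seed and are byte-reproducible; there is no hidden global random
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tkiscreen.datatypes import CountMatrix, PanelData
from tkiscreen.enrichment import GeneSetCollection

# Log-normal base-mean distribution (natural-log scale). Chosen to span a
# realistic dynamic range, including genes weak enough to fail the
# mean-FPKM > 1 expression filter.
BASE_MEAN_MEANLOG = 5.0
BASE_MEAN_SDLOG = 2.0


@dataclass
class PanelSimTruth:
    """Planted gene-drug couplings for the panel simulator.

    Each pair is (gene_id, drug_id, coupling) with coupling the AUC%
    change per unit log-expression; planted couplings must be strictly
    negative (higher expression -> lower AUC -> better response).
    """

    pairs: list[tuple[str, str, float]]
    noise_sd: float
    n_clipped: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for g, d, c in self.pairs:
            if c >= 0:
                raise ValueError(
                    f"planted coupling for ({g}, {d}) must be strictly negative"
                )


def gen_two_condition_counts(
    n_genes: int,
    n_reps: int,
    frac_up: float = 0.0,
    frac_down: float = 0.0,
    lfc: float = 2.0,
    dispersion: float = 0.1,
    seed: int = 0,
    conditions: tuple[str, str] = ("A", "C"),
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a two-condition count matrix with planted fold changes.

    Counts are negative binomial with per-gene base means drawn log-normal
    across genes and a single common dispersion (variance = mu + phi*mu^2).
    Exactly ``round(frac_up * n_genes)`` genes get their second-condition
    mean multiplied by ``2**lfc`` and ``round(frac_down * n_genes)`` by
    ``2**-lfc``. Gene lengths are uniform integers in [200, 10000] bases.

    Returns the count matrix and a per-gene truth table with columns
    ``is_deg``, ``direction`` (up/down/null), ``true_log2fc``, ``base_mean``.
    """
    if not (isinstance(n_genes, (int, np.integer)) and n_genes > 0):
        raise ValueError("n_genes must be a positive integer")
    if not (isinstance(n_reps, (int, np.integer)) and n_reps >= 2):
        raise ValueError("n_reps must be an integer >= 2")
    if not (0 <= frac_up < 1 and 0 <= frac_down < 1):
        raise ValueError("frac_up and frac_down must lie in [0, 1)")
    if frac_up + frac_down >= 1:
        raise ValueError("frac_up + frac_down must be < 1")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")

    rng = np.random.default_rng(seed)
    gene_ids = pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene_id")
    base_mean = rng.lognormal(BASE_MEAN_MEANLOG, BASE_MEAN_SDLOG, size=n_genes)
    lengths = rng.integers(200, 10001, size=n_genes)

    n_up = int(round(frac_up * n_genes))
    n_down = int(round(frac_down * n_genes))
    deg_idx = rng.choice(n_genes, size=n_up + n_down, replace=False)
    true_lfc = np.zeros(n_genes)
    true_lfc[deg_idx[:n_up]] = lfc
    true_lfc[deg_idx[n_up:]] = -lfc

    cond_a, cond_b = conditions
    sample_ids = [f"{cond_a}{i + 1}" for i in range(n_reps)] + [
        f"{cond_b}{i + 1}" for i in range(n_reps)
    ]
    condition = pd.Series(
        [cond_a] * n_reps + [cond_b] * n_reps,
        index=pd.Index(sample_ids, name="sample_id"),
        name="condition",
    )

    mu = np.empty((n_genes, 2 * n_reps))
    mu[:, :n_reps] = base_mean[:, None]
    mu[:, n_reps:] = (base_mean * 2.0**true_lfc)[:, None]
    # NB(r, p) with r = 1/phi, p = r/(r+mu) gives E=mu, Var=mu+phi*mu^2
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=condition.index),
        gene_lengths=pd.Series(lengths, index=gene_ids, name="length"),
        condition=condition,
    )
    direction = np.where(true_lfc > 0, "up", np.where(true_lfc < 0, "down", "null"))
    truth = pd.DataFrame(
        {
            "is_deg": true_lfc != 0,
            "direction": direction,
            "true_log2fc": true_lfc,
            "base_mean": base_mean,
        },
        index=gene_ids,
    )
    return cm, truth


def gen_panel(
    n_lines: int,
    candidate_genes: list[str],
    drugs: list[str],
    planted: PanelSimTruth | None = None,
    seed: int = 0,
) -> tuple[PanelData, PanelSimTruth]:
    """Simulate a cell-line panel with planted gene-drug couplings.

    Per-gene log-expression is i.i.d. normal (gene-specific mean in
    [2, 8], unit SD). The AUC% of a drug is its baseline plus the planted
    coupling times the (mean-centered) expression of each coupled gene
    plus Gaussian noise, clipped to [0, 100]; centering keeps the drawn
    baseline equal to the expected AUC so multi-gene couplings stay on
    scale. The number of clipped entries is recorded in the truth object.
    """
    if n_lines < 4:
        raise ValueError("n_lines must be >= 4 for defined correlation p-values")
    if planted is None:
        planted = PanelSimTruth(pairs=[], noise_sd=1.0)
    gene_set, drug_set = set(candidate_genes), set(drugs)
    for g, d, _ in planted.pairs:
        if g not in gene_set or d not in drug_set:
            raise ValueError(f"planted pair ({g}, {d}) references unknown gene or drug")

    rng = np.random.default_rng(seed)
    lines = pd.Index([f"CL{i:03d}" for i in range(n_lines)], name="cell_line")
    gene_means = rng.uniform(2.0, 8.0, size=len(candidate_genes))
    expr = pd.DataFrame(
        rng.normal(gene_means[:, None], 1.0, size=(len(candidate_genes), n_lines)),
        index=pd.Index(candidate_genes, name="gene_id"),
        columns=lines,
    )
    baseline = rng.uniform(40.0, 70.0, size=len(drugs))
    auc = np.tile(baseline[:, None], (1, n_lines)).astype(float)
    drug_pos = {d: i for i, d in enumerate(drugs)}
    for g, d, c in planted.pairs:
        centered = expr.loc[g].to_numpy() - expr.loc[g].mean()
        auc[drug_pos[d]] += c * centered
    if planted.noise_sd > 0:
        auc += rng.normal(0.0, planted.noise_sd, size=auc.shape)
    clipped = int(((auc < 0) | (auc > 100)).sum())
    auc = np.clip(auc, 0.0, 100.0)
    panel = PanelData(
        expr=expr,
        auc=pd.DataFrame(auc, index=pd.Index(drugs, name="drug_id"), columns=lines),
    )
    truth = PanelSimTruth(
        pairs=list(planted.pairs), noise_sd=planted.noise_sd, n_clipped=clipped
    )
    return panel, truth


def four_pl(dose, bottom: float, top: float, ic50: float, hill: float):
    """Four-parameter logistic: v(d) = bottom + (top-bottom)/(1+(d/ic50)^hill)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def doubling_doses(center: float, n: int = 9) -> np.ndarray:
    """``n`` doubling-dilution doses geometrically centered on ``center``.

    With the default n=9 the doses run from center/16 to 16*center.
    """
    if center <= 0:
        raise ValueError("center dose must be positive")
    half = (n - 1) // 2
    return center * 2.0 ** np.arange(-half, n - half)


def gen_dose_response(
    bottom: float,
    top: float,
    ic50: float,
    hill: float,
    doses,
    cv: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate CCK-8-style viability at the given doses.

    Viability is 4PL(dose) * (1 + eps) with eps ~ Normal(0, cv),
    i.e. multiplicative proportional noise. Returns a long table with
    columns dose, replicate, viability.
    """
    doses = np.asarray(doses, dtype=float)
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if top <= bottom:
        raise ValueError("top must exceed bottom")
    if (doses <= 0).any():
        raise ValueError("doses must be strictly positive")
    rng = np.random.default_rng(seed)
    clean = four_pl(doses, bottom, top, ic50, hill)
    rows = []
    for rep in range(1, n_reps + 1):
        eps = rng.normal(0.0, cv, size=doses.size) if cv > 0 else 0.0
        rows.append(
            pd.DataFrame(
                {"dose": doses, "replicate": rep, "viability": clean * (1.0 + eps)}
            )
        )
    return pd.concat(rows, ignore_index=True)


def gen_gene_sets(
    universe: list[str],
    n_sets: int,
    set_size: int,
    planted_set: list[str] | None = None,
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene sets sampled without replacement from the universe.

    An optional planted set (e.g. a DEG subset) is appended under the
    name ``planted`` to guarantee one enriched set.
    """
    if set_size > len(universe):
        raise ValueError("set_size exceeds universe size")
    rng = np.random.default_rng(seed)
    universe_arr = np.asarray(universe)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(n_sets):
        name = f"SET_{i:03d}"
        sets[name] = list(rng.choice(universe_arr, size=set_size, replace=False))
        descriptions[name] = "random set"
    if planted_set is not None:
        missing = set(planted_set) - set(universe)
        if missing:
            raise ValueError(f"planted set members outside universe: {sorted(missing)}")
        sets["planted"] = list(planted_set)
        descriptions["planted"] = "planted enriched set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def gen_drug_target_table(
    genes: list[str],
    drugs: list[str],
    density: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Random bipartite gene-to-drug annotation table.

    Each (gene, drug) association is an independent Bernoulli(density)
    draw; every drug is guaranteed at least one associated gene. Returns
    a two-column table (gene_id, drug_id).
    """
    if not genes or not drugs:
        raise ValueError("gene and drug lists must be non-empty")
    if not (0 < density <= 1):
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random((len(genes), len(drugs))) < density
    for j in range(len(drugs)):
        if not mask[:, j].any():
            mask[rng.integers(len(genes)), j] = True
    gi, dj = np.nonzero(mask)
    return pd.DataFrame(
        {
            "gene_id": np.asarray(genes)[gi],
            "drug_id": np.asarray(drugs)[dj],
        }
    )
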