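# Methods

## Scope and model of the data

The pipeline assumes a two-condition bulk RNA-seq design (parental vs
TKI-resistant cell line) with a small number of replicates per condition,
plus three external resources: a gene→drug annotation table, a cell-line
panel with both log-expression (genes × lines) and drug response
(drugs × lines, AUC% where lower means more sensitive), and dose-response /
flow-cytometry / wound-healing readouts for follow-up pharmacology. All
stages are deterministic functions of their inputs; the only randomness in
the package lives in the synthetic-data generators, which take explicit
seeds.

## Normalization

FPKM is computed as `10^9 · count / (length · library_size)` with the
library size defined as the column sum of the count matrix — the mapped
fragment total is not recoverable from a count matrix alone, and the column
sum is the standard proxy. Expression used downstream is
`log2(FPKM + pseudocount)` with pseudocount 1 (the most common convention;
it maps FPKM 0 to 0 and is recorded in the output object). The PCA QC
summary treats samples as observations, centers each gene by its mean and
does not standardize genes: variance proportions therefore reflect the raw
covariance structure of log expression. A constant matrix reports all-zero
proportions rather than failing, since that situation is a legitimate
degenerate QC outcome.

## Differential expression

Per gene, the pooled two-sample statistics are `log2FC = mean2 − mean1` and
the pooled within-condition variance `s²` on `df = n1 + n2 − 2` degrees of
freedom. The variance prior is a scaled inverse-χ²(d0, s0²) fitted by method
of moments on `log s²`: writing `e_g = log s_g² − ψ(df/2) + log(df/2)`, the
excess of `var(e)` over `ψ′(df/2)` identifies `d0` through the inverse
trigamma function (Newton iteration, tolerance 1e-10) and the mean of `e`
then identifies `s0²`. When the spread of `log s²` does not exceed its
sampling-theory expectation the prior degrees of freedom are infinite and
every gene is shrunk fully to `s0²`; in the fully degenerate case where all
`s²` are identical, `s0²` is reported as that common value. The moderated t
uses the posterior variance `s̃² = (d0 s0² + df s²)/(d0 + df)` on `d0 + df`
degrees of freedom. An ordinary pooled t (no shrinkage) is available via
`moderation=False` / `--no-moderation`.

Genes with zero posterior variance and nonzero fold change are flagged
degenerate with p reported as 0 — they carry infinite evidence under the
model and should be inspected rather than silently ranked.

This estimator was checked against the reference R implementation of the
same empirical-Bayes model (limma's `lmFit`/`eBayes`) on shared synthetic
data: prior parameters agree to 5 significant digits and per-gene t and p
to 1e-8 (see `tests/test_diffexpr.py`).

DE is computed on log2(FPKM+1), not on counts: no precision weights and no
mean-variance trend are applied. The practical consequence, visible in the
recovery tests, is a mild excess of false calls among well-expressed null
genes whose sampled |log2FC| exceeds 1 — the fold-change filter selects
exactly the null tail events. The reference implementation reproduces the
same calls on identical data, so this is a property of the model choice,
not of the code. DEG calling uses strict inequalities: FDR < 0.05,
|log2FC| > 1, mean raw FPKM (across all samples) > 1; the expression filter
uses raw FPKM, not log.

## Over-representation

ORA is a one-sided hypergeometric upper tail on the query/set overlap, with
sets intersected with the universe before testing and BH correction across
sets. The default universe is the set of genes passing the mean-FPKM filter
— enrichment against all annotated genes would inflate significance for
expression-biased sets. Up- and down-regulated DEGs are tested as one query
list by default.

## Drug screen

Each candidate gene (upregulated DEG with ≥1 annotated drug) is correlated
with each drug's AUC% across the cell lines common to the expression and
response matrices (pairwise deletion of missing entries, `n_used`
recorded). The p-value is the exact-null t transform
`t = r√((n−2)/(1−r²))` on `n−2` df, two-sided; Pearson is the default with
Spearman available as a flag. Hits require `r < −0.3` and `p < 0.001`,
both strict; no multiplicity correction is applied across pairs, matching
the screen's design as a candidate generator, and the implied expected
false-positive count (`n_pairs × 0.001`) is written to the log. Drugs are
kept with ≥ 4 distinct hit genes, ranked by hit count with ties broken by
drug id.

## Pharmacology

Dose-response curves use the four-parameter logistic
`v(d) = bottom + (top − bottom)/(1 + (d/IC50)^hill)`, fit by bounded
least squares in log-IC50 space. Initialization takes top/bottom from the
extreme per-dose means, hill = 1 and IC50 at the dose nearest the midpoint;
three further starts space IC50 log-uniformly across the dose range and the
best residual sum of squares wins, because doubling-dilution designs have
flat likelihood in hill and are prone to local minima. The lower asymptote
is bounded to `[0, 0.5·top]` by default — sparse dilution series rarely pin
it. Parameter tolerances are 1e-10; non-convergence of every start is
flagged on the returned fit, never silent. At least 4 distinct doses are
required and an all-equal viability vector is rejected as unidentifiable.

ICx inverts the fitted curve in closed form,
`Dx = IC50 · (x/(1−x))^(1/hill)`, with the effect fraction x normalized
between top and bottom; IC50 is recovered exactly at x = 0.5. The
combination index is `CI = d1/Dx1 + d2/Dx2` evaluated at the effect level
the combination achieved (the standard Chou–Talalay convention), classified
synergy/additive/antagonism at CI 1 with a 1e-9 tolerance — CI is a
continuous measure and the label at the knife edge is presentational.

Apoptosis and migration summaries are exact arithmetic on assay outputs:
apoptotic fraction = (late + early apoptotic events)/total; wound closure
`(w0 − w48)/w0` floored at 0 per well (wounds can widen when cells detach),
inhibition = 1 − closure_treated/closure_control, undefined when the
control does not close.

## Synthetic data: what it emulates and what it does not

`gen_two_condition_counts` draws negative-binomial counts
(variance `μ + φμ²`, one common dispersion, default φ = 0.1 — a typical
cell-line biological CV of ~32%) with per-gene base means log-normal
(meanlog 5, sdlog 2) so the dynamic range includes genes failing the
mean-FPKM filter, and plants exact ±lfc fold changes on a fixed count of
genes. It does not emulate per-gene dispersion trends, library-size
variation beyond what sampling induces, GC/length biases, or outlier
samples — so passing recovery tests demonstrate correctness of the
inference chain under a clean NB world, not robustness to real-data
artifacts.

`gen_panel` gives each gene i.i.d. normal log-expression (gene-specific
means in [2, 8], unit SD) and builds each drug's AUC% as a drawn baseline
(uniform 40–70) plus planted negative couplings times mean-centered
expression plus Gaussian noise, clipped to [0, 100]. Centering the
expression inside the coupling term absorbs a per-drug constant into the
baseline so that multi-gene couplings stay on the percent scale instead of
being flattened by clipping; the clipped-entry count is recorded in the
truth object. One structural consequence worth knowing: when one drug is
coupled equally to k genes, each single pair's population correlation is
capped near `−1/√k` no matter how strong the coupling, because the other
planted genes act as competing variance. At k = 6 and n = 144 lines this
puts pairs close enough to the −0.3 threshold that a drug reliably clears
the ≥4-hit keep rule but not always all six hits. Real co-regulated
resistance genes are positively correlated with each other, which would
raise per-pair correlations above this bound; the i.i.d. panel is the more
conservative test bed.

Recovery tests plant 12% of genes as DEGs (6% up, 6% down) at |log2FC| = 3
— a dense but realistic signal for a resistant line whose transcriptome is
heavily reprogrammed — and evaluate recall among planted genes that pass
the expression filter, since genes simulated below the FPKM floor are
undetectable by construction.

`gen_dose_response` applies multiplicative Gaussian noise
(`v·(1+ε), ε ~ N(0, cv)`) to exact 4PL values, emulating proportional
plate-reader error; it does not model edge effects or background
absorbance.

## Problem sizes

Default test and validation runs use 500–2000 genes, 3–5 replicates,
144-line panels with ≤ 400 drugs, 100-seed recovery loops and 10⁵-draw
Monte-Carlo calibrations — sizes chosen so the complete suite documents the
estimators' behavior in well under a minute while keeping Monte-Carlo
standard errors small relative to every asserted margin.

## Known limitations

- DE on log-FPKM without precision weights is anti-conservative for genes
  with very low counts; the mean-FPKM filter removes the worst cases but
  the |log2FC| filter still admits null tail events (quantified in the
  recovery tests at ≈1% of null genes).
- The screen's hit rule is a fixed-threshold heuristic; its false-positive
  behavior is characterized against a permutation oracle but no FDR is
  controlled across pairs, by design.
- 4PL fits assume viability normalized to untreated control in [0, ~1.5];
  raw absorbances are out of scope.
- The combination index uses single-agent fits only; it does not model
  dose-effect interaction surfaces.
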