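# Methods

This note documents the models and procedures implemented in `overlapnet`,
the defaults they ship with, the numerical choices made where the design was
genuinely open, and what the synthetic validation does and does not show.

## Input model

The pipeline assumes a balanced two-condition design: m genotypes, each with
r biological replicates under `control` and `treatment` (2·m·r samples), and
p phenotypic traits with one control and one treatment value per genotype.
The working signal throughout is the per-genotype log2 fold change (LFC) of
treatment over control — both for expression and for phenotypes — because
the scientific question is which genes *change together under treatment*,
not which genes are co-expressed at baseline.

## Stage A — normalization, filtering, log ratios

**Size factors.** Median-of-ratios: for sample j, the factor is the median
over reference genes of count<sub>ij</sub>/geomean<sub>i</sub>, where the
reference set is genes with a strictly positive geometric mean across all
samples (i.e. no zero counts). This is the standard count-normalization
estimator for library size and RNA composition bias; it is deliberately
dispersion-free (no count model is fit). Replicates are averaged by
arithmetic mean of normalized values.

**Filters.** Two rules on the averaged matrix D₂: genes whose 75th/25th
percentile ratio is below `quantile_ratio_max` (default 1.5) are
low-variance; genes with more than `low_expr_frac` (default 0.8) of columns
below `low_expr_value` (default 10) are low-expression. "Upper/lower
quantile" is read as the 75th/25th percentile with linear interpolation; a
zero 25th percentile with a positive 75th counts as an infinite ratio (the
gene passes the variance rule). After the LFC matrix L₀ is formed, a second
filter removes rows by LFC inter-quartile range against
`lfc_iqr_threshold` (default 0.25). The direction of this filter is
ambiguous in general usage — dropping unresponsive (low-IQR) genes serves
the workflow's intent, while the opposite direction is occasionally quoted —
so both are implemented behind `lfc_filter_mode`; the default is
`remove_low_variance`.

**Pseudocounts.** Expression log ratios use a pseudocount of 1 on the
normalized scale (zeros are common in counts); phenotype log ratios default
to pseudocount 0, since phenotype values are positive measurements, with a
hard error if any value is non-positive after the pseudocount.

## Stage B — co-expression network

Similarity is |Pearson correlation| between gene LFC rows: strong negative
co-regulation is biologically as informative as positive, so sign is
discarded. Soft thresholding raises similarities to an integer power β so
the weighted connectivity k<sub>i</sub> = Σ<sub>j≠i</sub> a<sub>ij</sub>
approaches a scale-free distribution. The fit statistic is the R² of the
regression of log10(frequency) on log10(mean connectivity) over 20
equal-width log10 bins (empty bins dropped, ≥3 required). `select_beta`
returns the smallest β > 1 reaching `r2_min` = 0.8, or the argmax-R² β with
a warning when none qualifies.

`beta_override` (default 3) pins the power directly, mirroring
`cutoff_override` (default 0.2): both shipped defaults come from the
reference analysis regime this tool targets (~90 genotypes, ~9,000 genes).
The override exists because on small or strongly modular datasets the
connectivity distribution is simply not scale-free at any power; the
argmax fallback is then essentially arbitrary (anywhere between 2 and 20 on
our synthetic studies) and the downstream edge set becomes unstable. Set
`beta_override: null` to use the scan.

**Cutoff.** The weighted adjacency is binarized by a strict `>` threshold;
isolated nodes are dropped. Without an override, the cutoff is chosen from a
grid as the smallest threshold minimizing network density among thresholds
retaining ≥5% of genes as non-isolated (an operationalization of the
"density minimum near the optimal cutoff" heuristic). The threshold applies
to a<sub>ij</sub> by default; `cutoff_scale: similarity` applies it to
s<sub>ij</sub> instead (equivalent to τ^(1/β) on the adjacency scale).

## Stage C — hierarchical link clustering

Link similarity between two edges sharing exactly one node is the Jaccard
index of the inclusive neighborhoods η(·) of the non-shared endpoints.
Similarities are computed as exact rationals (`fractions.Fraction`) so that
"equal similarity" is exact; single-linkage agglomeration processes all
merges at an equal level simultaneously, making the dendrogram independent
of link enumeration order. Links never merge across graph components, and
link pairs with no defined similarity never force a merge — the dendrogram
is a forest.

Partition density
D = (2/|E|) Σ_c |E_c| (|E_c|−|V_c|+1) / ((|V_c|−1)(|V_c|−2))
is evaluated incrementally after every merge level (each merge replaces two
community terms by the term of their union, with node sets merged
small-into-large). Communities with |V_c| = 2 (a single link) contribute 0 —
the formula is undefined there and a lone link carries no density
information. Ties in D resolve toward the higher-similarity (finer)
partition; the all-singletons leaf partition (D = 0) is included as a
candidate. Note that direct evaluation of the formula for one community of
two disconnected edges gives −1/3, not the −2/3 sometimes quoted as the
lower bound for that configuration; the implementation follows the formula.

Module ids are assigned by sorting community gene sets lexicographically, so
identical networks yield identical modules regardless of node labels or
input order. Modules with fewer than `min_module_size` genes (default 3)
are dropped; genes may then belong to zero, one, or several modules.

## Stage D — eigengenes and LASSO

A module's eigengene is the first right singular vector of its gene×genotype
LFC submatrix after z-scoring each gene row (so high-variance genes do not
dominate). The sign is fixed to correlate non-negatively with the mean
standardized row, falling back to the first gene's row when the mean is
numerically zero (‖mean‖ < 1e-10, e.g. perfectly anti-correlated pairs).

Trait association minimizes ‖y − Xα‖² + λ‖α‖₁ per trait, with eigengene
columns standardized and the response centered once on the full data
(glmnet-style; keeps the λ grid common across CV folds and the procedure
deterministic). Coefficients are reported on the standardized scale. The
solver is cyclic coordinate descent on the gram matrices, warm-started along
a 100-point log-spaced λ grid from λ_max = 2·max_j|x_jᵀy| (the KKT all-zero
threshold of this objective) down to 10⁻⁴·λ_max, stopping when the maximum
KKT violation falls below tol·scale (tol 1e-9 for final fits, 1e-6 inside
CV where held-out MSE is insensitive to trailing digits). The hot loop is
JIT-compiled with numba; a pure-Python fallback with identical semantics is
used if numba is unavailable.

λ is chosen by seeded 10-fold cross-validation. The default rule is
**1-SE** (largest λ within one standard error of the minimum mean CV MSE);
`lasso.rule: min` selects the plain minimum. The 1-SE default is a
deliberate design choice: with tens of genotypes and many strongly
correlated module eigengenes (overlapping modules share genes), the plain
minimum systematically over-selects — on synthetic studies it admitted up to
~20 modules for traits driven by 2 — while the 1-SE rule recovers compact,
near-causal module sets. Reference analyses in this regime likewise
report extreme sparsity (a handful of selected modules out of thousands).

Per-trait seeds derive deterministically from the global seed (seed + trait
index, reduced mod 2³¹).

## Stage E — enrichment and report

A gene is DEG when max_j |ℓ_ij| ≥ 2 (inclusive; a four-fold change in at
least one genotype). Enrichment uses the one-sided Fisher exact test
P(X ≥ a) with X hypergeometric over the post-filter gene universe (n₂
genes); degenerate margins return p = 1 by convention. The same test is
applied to an optional user-supplied list of known treatment-related genes;
the background universe for that test is likewise the n₂ post-filter genes,
and the report records the universe size used. No multiple-testing
correction is applied across traits (two validation tests, not a screen).

## Synthetic studies

`simulate.generate` emulates the target study design at desk scale.
Defaults (chosen once to represent a "strong signal" diversity-panel
experiment; all configurable):

| parameter | default | meaning |
|---|---|---|
| n_genes / m_genotypes / r_replicates | 1000 / 40 / 2 | study size |
| n_modules / module_size_range | 8 / (8, 15) | planted modules |
| overlap_prob | 0.3 | chance a module gene joins a second module |
| module_effect_sd / gene_noise_sd | 1.0 / 0.25 | planted-LFC signal vs noise (SNR 4) |
| nb_dispersion / baseline_log_mean / baseline_log_sd | 0.02 / 6.0 / 1.0 | count model |
| genotype_expr_sd | 0.6 | per-genotype baseline expression spread (log2) |
| sample_scale_factor_range | (0.7, 1.4) | true library-size factors |
| n_traits / causal_modules_per_trait / trait_noise_sd | 3 / 2 / 0.3 | trait model |

Module activities are standard normal over genotypes; member genes get
loadings of magnitude U(0.8, 1.2)·module_effect_sd with random sign (summed
over memberships for overlap genes); counts are Gamma–Poisson with variance
μ + 0.02·μ². `genotype_expr_sd` matters: without per-genotype baseline
variation, control expression is constant per gene and the quartile-ratio
variance filter removes essentially everything, which no real diversity
panel would do; the variation cancels exactly in the LFC ratio. The count
parameters keep count-level LFC noise (~0.23 sd) at or below the stated
biological noise so that `module_effect_sd/gene_noise_sd` is an honest
signal-to-noise ratio on the planted scale.

**What passing recovery tests show** — that the pipeline's stages compose
correctly and that planted co-response structure of realistic strength is
found (mean best-match module Jaccard ≈ 0.73, causal-gene Jaccard ≥ 0.5 in
~88% of seeds, size factors within ~1.5%). **What they do not show** — the
generator has no gene-length or GC effects, no batch structure, no
dispersion trends, a single overlap depth (≤2 modules per gene by
construction), and Gaussian module activities; absolute performance numbers
do not transfer to real data, and the scale-free stage is exercised only
via its override on these fixtures (planted-clique degree distributions are
not scale-free).

## Determinism and problem sizes

Identical inputs, config and seed give byte-identical run summaries
(summaries round-trip through JSON with sorted keys). Randomness enters
only through the synthetic generator and CV fold assignment, both driven by
explicit seeds. Tests and validation use 1,000-gene/40-genotype studies and
25 seeds for the recovery suite; graphs in the link-clustering oracle suite
have ≤12 links so a naive O(L³) single-linkage reference stays exact.

## Known limitations

* The dendrogram is materialized from all pairwise link similarities of
  edges sharing a node; extremely dense networks (≫10⁵ links) would need a
  sparse-similarity implementation.
* Weighted link clustering (similarity on edge weights) is not implemented;
  the clustering operates on the binarized network.
* The LASSO reports standardized coefficients only; no inference (p-values,
  stability selection) is attached to module selection.
* Phenotype log ratios assume strictly positive trait values.
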