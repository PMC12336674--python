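# Methods

`gicmp` implements a multi-sample intratumour-heterogeneity workflow for
single-cell RNA-seq cohorts spanning several cancer types (oesophageal,
gastric, colorectal — "GIC" collectively): per-sample NMF discovery of
epithelial gene programs, robustness filtering and clustering into
meta-programs (MPs), rank-based cell scoring and identity assignment,
tissue-enrichment statistics, and compositional analysis of the
microenvironment (niche clustering, reference-correlation lineage
inference, metaplasia grouping). A synthetic-cohort generator with full
ground truth underpins every test.

## Quality control and normalization

A cell is removed iff it detects fewer than 500 genes, more than 6000
genes, or more than 20% of its UMIs come from mitochondrial genes; all
inequalities are strict in the removal direction (a cell detecting exactly
500 genes is kept). "Detected" means count > 0. A gene is kept iff
detected in strictly more than 10 cells. Samples enter program discovery
iff they retain at least 50 epithelial cells. When a cell violates several
rules it is counted under the first matching rule in the fixed precedence
(pre-computed doublet flag, low genes, high genes, high mito); the
precedence affects only the per-rule bookkeeping, never the retained set.
Doublet calls are accepted as a boolean flag rather than re-derived.

Normalization is per-cell depth scaling to 10,000 UMIs followed by log1p
— the ecosystem default; the target sum is configurable. Raw counts are
preserved in a layer.

## Per-sample NMF and the robustness filter

For each retained sample, the epithelial cells are reduced to the top 7000
genes by mean normalized expression (mitochondrial and ribosomal genes
excluded — by `var` flags or MT-/RPL/RPS symbol prefixes), z-scored per
gene and clipped at zero. Rank-K NMF (scikit-learn coordinate descent,
random non-negative init, fixed seed) is fitted for every K in 4..9, and
each factor is summarized by its 50 highest-loading genes, so every sample
yields exactly 4+5+...+9 = 39 programs. Ties in loadings resolve by gene
symbol, making signatures deterministic.

Program similarity for the filter is the shared-gene fraction of the fixed
signature size (|A∩B|/50). A program is **robust** iff

1. at least one other program of the same sample shares ≥ 50% of its
   genes (the recurrence of a factor across K values within one tumour);
2. it shares ≥ 20% of its genes with some program of a different sample;
3. it survives a within-sample redundancy sweep: candidates are visited in
   order of decreasing cross-sample support (number of other-sample
   programs at the 20% bar; ties broken by larger maximal within-sample
   share, then lexicographically by sample/K/factor) and dropped if they
   share > 20% with an already-kept program of the same sample.

The visiting order makes the greedy selection independent of input order;
the whole filter is checked against a plain-loop brute-force
implementation on randomized collections.

## Meta-programs, consensus signatures, abundance

Robust programs are clustered by average-linkage hierarchical clustering
on 1 − Jaccard distance. Two cuts are supported: a fixed number of
clusters (the curated-cut style) and a distance threshold, default 0.8,
i.e. clusters keep merging while their average Jaccard similarity stays
above 20% — the same bar the robustness filter uses for "similar". The
threshold cut is the pipeline default because it is robust to stray
singleton programs, which under a fixed cluster count can hijack a cluster
and force two genuine program families to merge. Manual curation is
reproduced as declarative overrides (merge listed clusters, reassign
listed programs), never interactively.

An MP's consensus signature ranks genes by (number of member programs
containing the gene, mean within-member rank, symbol) and keeps the top
50; for MPs with at least two members only genes occurring in ≥ 2 members
qualify, so a consensus can be shorter than 50.

Per (MP, cancer type), abundance is A = log2((observed+1)/(expected+1)),
where observed counts the MP's member programs from that cancer type and
expected = (MP size) × (cancer type's share of all robust programs).
Significance is a two-sided binomial test of the observed count at that
share, Bonferroni-adjusted over all pairs. Levels: absence (observed = 0),
low (A < 1), medium (1 ≤ A < 2), high (A ≥ 2); boundary values fall
upward. Functional annotation uses the one-sided hypergeometric
over-representation test against GMT gene-set collections with
Benjamini–Hochberg adjustment.

## Cell scoring, identity, Ro/e

Per-cell MP activity is the normalized area under the gene-set recovery
curve within the top-ranked fraction of the cell's genes: with genes
ranked by decreasing expression (ties by ascending gene identifier) and
k = ceil(0.05 × n_genes), AUC = Σ_{r=1..k} |set ∩ top-r|, normalized by
Σ_{r=1..k} min(r, |set|). The score lies in [0,1] and depends only on
ranks, hence is invariant under any strictly monotone transform of the
expression vector. The 5% rank threshold is the reference algorithm's
default and is configurable; deterministic tie-breaking replaces
randomized ties for reproducibility. A second scorer (mean set expression
minus expression-matched control genes drawn from 25 mean-expression bins,
fixed seed) is provided behind the same interface as an independent
validation.

Per-sample MP activity is the median score over the sample's epithelial
cells (medians are restricted to epithelial cells, matching the scoring
population). A cell's identity is the argmax over MPs after subtracting
each MP's mean score across cells; exact ties resolve to the lowest MP
column index.

Ro/e is observed / expected cell counts in a group × category contingency
with the chi-squared expectation row_total × col_total / grand_total;
cells with zero expectation are reported as missing, never divided.
Enrichment is strict (Ro/e > 1).

## Composition, niches, lineage, metaplasia

Relative abundance of a cell subtype is its count divided by its parent
major cell type's count within the sample; (sample, major type)
compartments with fewer than 50 cells are excluded from abundance
comparisons. Scaled abundance is the per-subtype z-score across samples
(zero-variance columns scale to zeros).

Niche clustering operates on samples with ≥ 50 epithelial **and** ≥ 50
immune cells. Subtypes with fewer than 100 cells in total, or with more
than 30% of their cells from a single sample, are dropped. The feature
matrix is the within-major relative abundances of retained non-epithelial
subtypes — computed directly from counts, since the niche stage defines
its own sample filter and no per-compartment rule — optionally
concatenated with per-sample epithelial MP-identity fractions; all columns
are z-scored jointly. Sample distance is 1 − Pearson correlation of
feature vectors; the tree is Ward linkage (scipy's `ward` on the
precomputed condensed distances, the closest available analogue of R's
`hclust(..., "ward.D")`) cut at the requested number of groups.

Lineage inference correlates each epithelial cell (log-normalized UMI
shares) against reference lineage profiles over the union of reference
signature genes present in the data. With PCC the Pearson coefficient:

1. if any lineage with PCC > 0.3 shares the cell's cancer-type tissue of
   origin, assign the best such lineage (*same-cancer*);
2. else if the best PCC > 0.3 lineage is from another GI tissue, assign it
   (*other-GIC*);
3. else if all PCC ≤ 0.3 and the top-5 lineages contain no GI lineage,
   label *Non-GI*.

Two situations the three rules leave open are resolved deterministically:
all PCC ≤ 0.3 but a GI lineage in the top-5 assigns the best such lineage
flagged *low-confidence*; a best correlate above 0.3 that is a non-GI
reference yields *Non-GI* (rule *non-GI-correlated*), consistent with
collapsing all non-GI lineages into one category.

Metaplasia grouping computes, per sample, the proportion of assigned
epithelial cells whose lineage tissue is foreign epithelium for the
sample's cancer type: intestinal lineages for gastric samples, gastric
plus intestinal for oesophageal ones (colorectal samples have no
metaplastic tissue defined and always fall in the non-metaplastic group).
The "auto" threshold is the exact 1-D two-class split: an exhaustive scan
over sorted proportions minimizing within-class sum of squares, with the
threshold at the midpoint of the two class means. This is the global
optimum of 1-D 2-means and needs no seed; a fixed numeric threshold is
honoured when given (metaplastic iff proportion ≥ threshold).

## The synthetic cohort generator

Counts follow a gamma-Poisson (negative binomial) model: log-normal
baseline gene means (σ = 1), gene-level dispersion 0.3, per-cell library
sizes uniform in 1500–4000 UMIs. A dedicated mitochondrial block (2% of
genes, MT- prefixed) is rescaled per cell to hit a target mitochondrial
UMI share drawn from 1–10%; a ribosomal block (3%, RPL/RPS prefixed)
exercises the flag-by-prefix paths. Default cohort: 12 samples cycling
through three cancer types, 200–300 cells each, half epithelial, 2000
genes.

Planted programs are disjoint 50-gene sets among non-flagged genes — 4
shared across all samples plus 1 private per sample — whose genes are
activated ×exp(2) (≈ 7.4-fold) in program-active epithelial cells.
Activity is mutually exclusive per cell (15% of a sample's epithelial
cells per program) so each active cell has a single expected MP identity;
the generator rejects specs where programs × active_fraction exceeds 1.

Composition groups assign each sample one of two non-epithelial subtype
mixtures. Because the niche features are *within-major-type* relative
abundances, the default mixtures differ in within-major proportions (e.g.
CD4- vs CD8-dominated T compartments), not merely in major-type totals —
a signal that the relative-abundance normalization would otherwise
remove.

For lineage tests, a bundled synthetic reference atlas provides six GI
lineages (two per GI tissue) and six non-GI lineages, each a low uniform
background plus an elevated 20-gene marker block. Lineage cells are a
profile plus Gaussian log-scale noise. "Background" cells — the stand-in
for epithelium of no single GI lineage — are a flat mixture of the non-GI
profiles blurred with SD 0.4, which places them in the rule-3 regime (all
PCC ≤ 0.3, top-5 non-GI). Truly uncorrelated random cells would have a
randomly ordered top-5 and mostly land in the low-confidence residual
rule instead; that behaviour is inherent to the top-5 condition, not to
this implementation.

What the generator does **not** emulate: batch effects, ambient RNA,
doublets (beyond an externally supplied flag), gene–gene correlation
beyond the planted programs, and realistic gene-length/GC biases. Passing
tests therefore demonstrate the pipeline's correctness and its ability to
recover planted structure under over-dispersed counting noise — not
robustness to the technical artefacts of real cohorts.

## Problem sizes and numerical choices

Tests and the acceptance script run the full pipeline on the default
12-sample cohort (~3000 cells × 2000 genes; 72 NMF fits), chosen to keep
a complete run in tens of seconds while leaving every stage's statistics
well-determined. NMF uses max_iter = 400, tol = 1e-4; non-convergence
warns and emits the final iterate. Zero-variance genes z-score to zeros;
zero-expectation Ro/e cells are missing, not infinite; empty inputs raise
errors naming the offending field or cell.

## Known limitations

* The NMF solver is scikit-learn's coordinate descent, not the sparse-NMF
  variant some pipelines use; signatures are defined by top loadings and
  are empirically stable to this choice, but factor weights differ.
* "Several similar programs within the tumour" is operationalized as ≥ 1
  within-sample partner at the 50% bar (configurable).
* Criteria 2–3 of the robustness filter use shared-gene fraction; Jaccard
  is reserved for MP clustering. With equal-size signatures the two are
  monotone-related but numerically different.
* The niche feature matrix scales subtype abundances and MP-identity
  fractions jointly; a flag allows separate scaling.
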