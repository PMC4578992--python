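# Methods

This note documents the models and procedures implemented in `lncbcell`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not establish.

## Probe-set remapping

Exon-array probes were designed against older genome annotation, so the
package rebuilds gene-level probe sets against current gene models. A probe
is assigned to a gene iff its interval is fully contained in at least one
exon of at least one of the gene's transcripts *and* the probe strand
matches the gene strand. Containment is tested per transcript rather than
against a per-gene merged exon union, so a probe inside any single
transcript's exon qualifies even under alternative splicing. Strand
specificity matters because the analysis distinguishes antisense genes
that overlap sense genes: a strand-agnostic rule would pool their signals.
Probes contained in no gene are `not_contained`; probes contained in two or
more distinct genes are `ambiguous` and dropped, since their signal cannot
be attributed. Probe sets with fewer than `min_probes = 4` probes are
excluded — "fewer than 4" operationalizes the exclusion of 1–3-probe sets,
which are too small for a robust median polish.

## Summarization (RMA-style)

Raw linear intensities are log2-transformed, quantile-normalized jointly
over all assigned probes (each column is mapped onto the mean of the
column order statistics; ties receive the mean of the reference values at
their rank positions, so within-column order is preserved weakly), and
summarized per gene by median polish of the additive model
`log2 I_ps = μ + α_p + β_s` (tolerance 1e-6 on the largest sweep update,
at most 50 iterations; the reported per-sample value is `μ + β_s`). The
classic RMA background-correction convolution is *not* applied: the
operative background treatment in this analysis is the explicit detection
threshold against antigenomic probes (below), and the convolution step is
not identifiable from summarized data.

## Detection and variance filtering

Antigenomic control probes match no genomic sequence and measure optical
background plus GC-dependent nonspecific hybridization. To compare genes
against a background of the same structure, constructed background probe
sets are sampled to match real probe sets in probe count and GC-content
distribution: real sets are cycled round-robin; for each, background
probes are drawn without replacement within GC bins of width 0.05
(nearest non-exhausted bin as fallback), then summarized with the same
median polish. The detection threshold is `τ = mean + 2·SD (ddof 1)` over
all pooled per-sample summaries of all draws (default 1000 draws; pooling
across samples and draws is our resolution of an otherwise open choice —
per-sample thresholds change results negligibly at this noise level). A
gene is detected iff it exceeds τ (strictly) in every sample of at least
one B-cell subset — the subset structure is what makes stage-restricted
genes detectable. Separately, genes with expression SD (ddof 1) below 0.5
across all samples are removed as uninformative for co-expression.
Sample SD uses ddof 1 throughout because per-subset n is 6–7.

## Neighbor pairs

All unordered same-chromosome gene pairs with a span gap ≤ 1000 bp
(inclusive; overlap counts as gap 0) are catalogued. 5'/3' ends are
strand-determined; for opposite-strand overlapping pairs, head-to-head
means both 5' ends fall in the overlap, tail-to-tail both 3' ends, and
containment of one span in the other is fully-overlapping; remaining
overlaps are `partial_other`. Geometry uses gene spans only; exon overlap
is recorded as a separate boolean. Pair classes (antisense–mRNA,
lincRNA–mRNA, mRNA–mRNA) come from the Ensembl-style biotypes. Pearson
correlation over all samples quantifies co-expression per pair;
zero-variance members flag the pair and exclude it from class summaries.

## Sample clustering and Baker's Gamma

Samples are clustered by average linkage (UPGMA) on Pearson correlation
distance `d(s,t) = 1 − r(s,t)` computed over a gene class (protein-coding,
all lncRNA classes, lincRNA only, antisense only), using the genes that
survive both filters — the gene set actually carried into all module
analyses. UPGMA uses scipy's implementation, which is deterministic for
fixed input. Baker's Gamma between two trees on the same samples is the
tie-aware Spearman correlation, over all unordered leaf pairs, of the
merge step at which the pair first shares a cluster; merge steps (not raw
heights) make the coefficient invariant to monotone height transforms.

## Weighted co-expression network

Unsigned adjacency `a_ij = |cor(x_i, x_j)|^β` with β = 6 by default (the
conventional unsigned-network default; a signed mode `((1+r)/2)^β` is
available but off). `pick_soft_threshold` reports, per candidate β, the
signed R² of the log–log regression of binned connectivity frequency on
mean connectivity (10 equal-width bins) and selects the smallest β
reaching R² ≥ 0.8, falling back to the argmax with a warning. The
topological overlap matrix is
`ω_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with
`ℓ_ij = Σ_{u≠i,j} a_iu a_uj` and `k_i = Σ_{u≠i} a_iu`.

Modules are branches of the average-linkage tree on `1 − ω` under a static
height cut at `cut_height × max merge height`, with clusters smaller than
`min_module_size = 30` left grey and surviving clusters colour-labelled by
decreasing size (turquoise, blue, brown, ...). The default
`cut_height = 0.95` was calibrated on simulated data: genes with no
planted structure attach to module branches only in the top few per cent
of the height range (their topological overlap is inflated by the
`min(k)` normalization at low connectivity), while planted modules are
complete well below it; recovery is flat for cuts anywhere in ~0.90–0.96,
so the default sits inside that plateau. The dynamic hybrid tree cut used
by the reference WGCNA implementation is intentionally out of scope; the
cut is configurable. Module eigengenes are the first right singular
vector of the row-standardized module submatrix, sign-oriented to
correlate positively with the mean member profile, with
`variance_explained = s₁²/Σs²`. Modules whose eigengenes cluster below
`merge_height = 0.25` (dissimilarity 1 − cor, average linkage) are merged
once and eigengenes recomputed. Intramodular connectivity is the
within-module adjacency row sum; hubs are the top-kWithin genes of a
module with ties broken by gene id.

## Eigengene correlations, biotype tables, GO

Per-gene Pearson and Spearman correlations to the own-module eigengene use
the t approximation `t = r√((m−2)/(1−r²))` with m−2 degrees of freedom for
both coefficients (a permutation oracle in the tests confirms the
approximation at m = 72). Module × biotype tables fold small ncRNAs into
the other-lncRNA column to give the five canonical columns. GO
overrepresentation uses the upper-tail hypergeometric probability with the
universe defined as network genes carrying at least one annotation —
standard overrepresentation practice — and Benjamini–Hochberg adjustment
within each module; both raw p and q are reported, with raw p < 0.01 as
the default reporting threshold.

## FACS gating trees

A gate is a two-marker quadrant rule: thresholds `t_x, t_y` combined as
`(x ≥/< t_x) AND/OR (y ≥/< t_y)` — 8 rule forms, inequalities inclusive on
"≥". Thresholds range over empirical quantiles of the node's events (5%
to 95% in 5% steps *plus the data extremes*, so a rule can collapse to a
single effective threshold — the common case in practice where one marker
suffices). The search is exhaustive over marker pairs × thresholds ×
forms and maximizes the Gini impurity decrease; impurity decreases are
rounded to 12 decimals so that mathematically tied candidates fall to the
deterministic tie-break (marker pair lexicographic, then t_x, t_y, then
rule-form index) rather than to floating-point noise. Trees recurse to
depth ≤ 3 (≤ 8 leaves — sufficient for 5–6 subsets per tissue), stopping
at purity or when no split improves; leaves carry the majority label. The
quadrant-rule family and quantile grid are our operationalization of
"a simple binary decision based on the fluorescence levels of two surface
markers"; oblique (linear-combination) rules are out of scope.

## Synthetic study generator

The generator emulates the study's design with controlled ground truth.

**Design.** 72 arrays: 7 bone-marrow donors × {pre-B1, pre-B2, immature,
naive, memory, plasma cell} and 6 tonsil donors × {naive, centrocyte,
centroblast, memory, plasmablast}. ~2000 genes split over six biotype
classes in proportions mirroring a whole-genome array (protein-coding 990,
lincRNA 280, antisense 210, small ncRNA 100, other lncRNA 30, pseudogene
390 — the genome-wide class proportions scaled down ~19×).

**Genome.** Two chromosomes; genes 2–10 kb with 1–4 exons (exons ≥ 200 bp,
introns ≥ 100 bp), inter-gene gaps ≥ 2 kb so no accidental <1 kb pairs
arise. Planted pairs: 30 sense–antisense pairs (10 each head-to-head,
tail-to-tail, fully overlapping) simulated at r = 0.8; 30 lincRNA–mRNA and
30 mRNA–mRNA neighbors at gaps < 1 kb with r = 0.4 and 0.25; 20 control
pairs at gaps 1.2–1.8 kb with independent expression. Coordinates are
0-based half-open internally; GTF I/O converts to 1-based inclusive.

**Modules.** 7 planted modules with uneven sizes (500, 200, 150, 110, 80,
60, 45), echoing the skewed size spectrum of real co-expression module
tables. Module profiles are mutually orthogonal hierarchical
developmental contrasts over the 11 subsets — tissue (the dominant
module), early-B development, germinal center, pre-B vs immature,
plasma-cell differentiation, a naive–memory axis with fine pre-B1/pre-B2
and centrocyte/centroblast contrasts, and a plasmablast program — scaled
to unit variance across subsets. The block structure gives the implied
sample hierarchy decisive margins (tissue splits first), which is what
real B-cell dendrograms show; with generic smooth gradients the top
merges are near-ties and tree comparisons become unstable. Module genes
are drawn from every biotype class proportionally to class abundance
(stratified allocation), as real modules mix all biotypes; eigengene
values are the subset profile plus an additive per-donor offset
(SD 0.2) so clustering by subset rather than donor is non-trivial.
Gene-level log2 expression is `baseline + sign·loading·e_m(s) + ε` with
baselines uniform on [6.5, 10], 25% negative loadings, ε ~ N(0, 0.65),
and the loading calibrated per module so the mean within-module pairwise
correlation is `within_module_cor` (default 0.7; the realized value on
the default study is within ±0.02). Probe intensities add a per-probe
affinity offset (SD 0.3) and probe noise (SD 0.25), exponentiated to the
linear scale.

**Background and filter failures.** 1000 antigenomic probes with GC
uniform on [0.15, 0.85] and log2 level `4.0 + 2.0·(GC − 0.5) + N(0, 0.3)`;
the GC slope makes GC matching in the filter stage consequential. 30
genes are planted below the background regime (log2 ≈ 3) and 30 with
SD ≈ 0.15 < 0.5; both sets are disjoint from module genes. Unstructured
("grey") genes get per-gene SDs uniform on [0.3, 0.9], so roughly half
pass the variance filter and enter the network as genuine negatives.

**FACS.** Events are lognormal per subset × marker with stylized levels
low = 1 and high = 3 (5 for the very bright CD38 of antibody-secreting
cells) in natural-log units at scale 0.15, i.e. >13σ between levels:
cleanly sorted, non-overlapping populations, balanced across subsets
(10⁴ events per tissue, remainder dropped). The level matrix is chosen so
every subset is separable from its neighbours by at least one marker
pair; the marker semantics are approximate (e.g. CD19 is coded high only
on precursors), which matters to none of the algorithms.

**What the synthetic tests do not show.** The generator produces Gaussian
log-intensities with a single latent factor per module, exactly matched
probe behavior, no batch effects, no cross-hybridization, no doublets or
spillover in FACS, and class-balanced, well-separated populations. Passing
recovery tests therefore demonstrates correctness of the computations and
sane behavior of the default parameters — not robustness to the messier
failure modes of real arrays or cytometry.

## Numerical choices and degenerate inputs

- Quantile normalization: ties get the mean reference value at their rank
  positions (weak rank preservation).
- Median polish: single-probe sets return the probe row unchanged.
- Detection is strict (`> τ`); variance retention is inclusive (`SD ≥ 0.5`),
  the literal reading of "remove genes with SD < 0.5".
- Correlation distance raises on zero-variance sample vectors (filters
  prevent them in the pipeline).
- Eigengene sign for perfectly anti-correlated two-gene modules (mean
  profile zero) is left as computed; variance explained is still 1.
- Empty edge selections, empty pair classes, and zero-event FACS tables
  return empty outputs, not errors.
- All randomness derives from one seed; pipeline stages draw from
  independent substreams keyed by stage name, so toggling one stage does
  not shift another's stream.

## Problem sizes

Default synthetic study: ~2000 genes × 72 samples, ~35k probes, 1000
background draws, 10⁴ FACS events per tissue. The full pipeline runs in
well under a minute on one CPU; the test suite (including two full
pipeline runs and all oracle comparisons) in a few minutes.

## Known limitations

- Static module cut instead of dynamic hybrid tree cut; very close or
  nested modules that the dynamic cut separates may merge or stay grey.
- The scale-free fit uses equal-width connectivity bins; WGCNA's equal-
  count binning can give slightly different R² values.
- Baker's Gamma compares merge steps globally; trees over very different
  gene sets with similar topology can still disagree through branch
  interleaving.
- GO enrichment has no term-graph propagation (no true-path rule) and no
  conditional (elim-style) testing.
- FCS binary ingestion is delegated to an external adapter producing CSV;
  only the CSV event-table interface is implemented here.
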