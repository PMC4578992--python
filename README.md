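# lncbcell

Long noncoding RNAs (lncRNAs) are differentially expressed across the stages
of human B-cell development, but almost none of them have known functions.
`lncbcell` implements a reusable, tested version of the analysis used to
profile lncRNAs in flow-sorted B-cell subsets on exon arrays and to infer
candidate functions by *guilt by association*: a lncRNA embedded in a
co-expression module of well-characterized protein-coding genes inherits the
module's biological annotation as a hypothesis.

The pipeline covers, end to end:

1. **Probe-set remapping** — array probes are re-assigned to current gene
   models: a probe belongs to a gene only if it is fully contained in an
   exon of one of the gene's transcripts on the same strand; ambiguous
   probes are dropped and probe sets with fewer than 4 probes are excluded.
2. **RMA-style summarization** — log2 transform, quantile normalization
   across arrays, and per-gene median-polish summarization of the additive
   model `log2 I_ps = μ + probe_p + sample_s`.
3. **Detection and variance filtering** — background probe sets are
   constructed by resampling antigenomic control probes to match each real
   probe set's size and GC distribution; the detection threshold is
   `τ = μ_bg + 2σ_bg` over the pooled constructed-set summaries, a gene is
   detected if it exceeds τ in *every* sample of at least one B-cell
   subset, and genes with expression SD < 0.5 across samples are removed.
4. **Neighbor-pair co-expression** — all gene pairs within 1 kb on the
   genome are catalogued (head-to-head / tail-to-tail / fully overlapping
   sense–antisense geometry, exon overlap, biotype pair class) with their
   Pearson correlation over samples.
5. **Sample-dendrogram comparison** — average-linkage clustering of samples
   on Pearson correlation distance `d = 1 − r`, per gene biotype class, and
   Baker's Gamma (rank correlation of pairwise first-merge steps) between
   class-specific trees.
6. **Weighted co-expression network** — unsigned soft-threshold adjacency
   `a_ij = |cor(x_i, x_j)|^β` (default β = 6, scale-free fit diagnostics
   included), topological overlap `ω_ij = (ℓ_ij + a_ij) / (min(k_i,k_j) +
   1 − a_ij)`, average-linkage module detection on `1 − ω`, module
   eigengenes (first principal component of the standardized module),
   module merging, intramodular connectivity `kWithin`, hub genes, and
   Cytoscape-ready edge export.
7. **Module reporting** — per-lncRNA Pearson/Spearman correlation to the
   module eigengene with t-based p-values, module × biotype count tables,
   and GO-term overrepresentation by the upper-tail hypergeometric test
   with Benjamini–Hochberg adjustment.
8. **FACS gating trees** — recursive partitioning of labelled flow-
   cytometry events with two-marker quadrant rules (thresholds on an
   empirical-quantile grid, AND/OR combinations, each inequality
   flippable), chosen by exhaustive search to maximize the Gini impurity
   decrease, depth ≤ 3.

Because the original arrays live in external repositories, the package
ships a first-class **synthetic study generator** that emulates the study
design — 72 arrays (7 bone-marrow donors × 6 subsets, 6 tonsil donors × 5
subsets), ~2000 genes in six Ensembl-style biotype classes, 7 planted
co-expression modules with subset-specific eigengene profiles, planted
sense–antisense and neighbor pairs, GC-dependent antigenomic background
probes, and per-subset lognormal FACS marker distributions — with full
ground truth, so every stage is tested as a recovery problem.

## Worked example

```python
from lncbcell.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1, outdir="demo_run"))
print(round(report["results"]["tau"], 3))  # 4.323  (detection threshold, log2)
print(report["stages"]["network"]["module_sizes"])
# {'grey': 580, 'turquoise': 498, 'blue': 194, 'brown': 147, 'yellow': 108,
#  'green': 80, 'red': 58, 'black': 43}
print(report["results"]["facs"]["bone_marrow"])
# {'resubstitution_accuracy': 0.9996998799519808, 'depth': 3}
```

The run writes the simulated inputs (GTF gene models, probe table,
intensity matrix, FACS event CSVs), the gene-level expression matrix, the
filter report, the local-pair catalogue, per-class sample dendrograms in
Newick format with Baker's Gamma comparisons, module assignments with
eigengenes and connectivity, the module × biotype table, GO enrichment,
and the fitted gating trees under `demo_run/`.

Interpretation of the numbers above: the detection threshold 4.32 log2
units sits two standard deviations above the GC-matched antigenomic
background; the seven detected modules (grey = unassigned) recover the
seven planted expression programs; and the depth-3 gating tree separates
the six bone-marrow subsets with 99.97% resubstitution accuracy.

A command-line interface mirrors the stages:

```bash
lncbcell simulate --outdir sim --seed 2
lncbcell remap --gtf sim/gene_models.gtf --probes sim/probes.tsv --out map.tsv
lncbcell rma --intensities sim/probe_intensities.tsv --map map.tsv \
             --metadata sim/sample_metadata.tsv --out expr.tsv
lncbcell facs-tree fit --events sim/facs_bone_marrow.csv --tree tree.json
lncbcell run-all --outdir full_run --seed 1
```

## Layout

- `src/lncbcell/synthetic_data.py` — study generator and ground truth
- `src/lncbcell/remap.py`, `io.py` — gene models, probe assignment
- `src/lncbcell/preprocess.py` — quantile normalization, median polish, RMA
- `src/lncbcell/filters.py` — background construction, detection/variance filters
- `src/lncbcell/annotate.py` — coding-potential summaries, neighbor pairs
- `src/lncbcell/cluster_compare.py` — sample trees, Baker's Gamma
- `src/lncbcell/coexnet.py` — adjacency, TOM, modules, eigengenes, hubs
- `src/lncbcell/downstream.py` — eigengene correlations, biotype tables, GO
- `src/lncbcell/facs_gate.py` — Gini gating trees
- `src/lncbcell/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
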