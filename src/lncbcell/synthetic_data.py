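"""Synthetic study generator: gene models, probes, intensities, FACS events.

Emulates an exon-array profiling study of sorted human B-cell subsets:
72 arrays (7 bone-marrow donors x 6 subsets, 6 tonsil donors x 5 subsets),
~2000 genes in six Ensembl-style biotype classes, planted co-expression
modules with subset-specific eigengene profiles, genomic neighbor and
sense-antisense structure, GC-dependent antigenomic background probes,
and per-subset lognormal FACS marker distributions.

Every quantity is planted with known ground truth so that downstream
stages (remapping, detection filtering, module discovery, gating trees)
can be tested as recovery problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import write_gtf, write_matrix_tsv, write_tsv
from .models import ALL_SUBSETS, BIOTYPES, SUBSETS_BM, SUBSETS_TONSIL, GeneModelSet

PROBE_LENGTH = 25

BM_MARKERS = ("CD10", "CD19", "CD20", "CD27", "CD34", "CD38", "CD45")
TONSIL_MARKERS = ("CD3", "CD10", "CD20", "CD27", "CD38", "CD44", "CD45", "CXCR4")

# Per-subset lognormal locations (natural-log units) of surface-marker
# fluorescence.  Levels are stylized to low=1 / high=3 (5 for the very
# bright CD38 of antibody-secreting cells); with scale 0.15 adjacent levels
# are >13 sigma apart, i.e. cleanly sorted, non-overlapping populations.
# Each subset is distinguishable from its developmental neighbours by at
# least one marker pair, so two-marker quadrant gates can isolate every
# population.
_BM_LOCS = {
    "preB1":       {"CD10": 3, "CD19": 3, "CD20": 1, "CD27": 1, "CD34": 3, "CD38": 1, "CD45": 1},
    "preB2":       {"CD10": 3, "CD19": 3, "CD20": 1, "CD27": 1, "CD34": 1, "CD38": 1, "CD45": 3},
    "immature":    {"CD10": 3, "CD19": 3, "CD20": 3, "CD27": 1, "CD34": 1, "CD38": 1, "CD45": 3},
    "naive_bm":    {"CD10": 1, "CD19": 1, "CD20": 3, "CD27": 1, "CD34": 1, "CD38": 1, "CD45": 3},
    "memory_bm":   {"CD10": 1, "CD19": 1, "CD20": 3, "CD27": 3, "CD34": 1, "CD38": 1, "CD45": 3},
    "plasma_cell": {"CD10": 1, "CD19": 1, "CD20": 1, "CD27": 3, "CD34": 1, "CD38": 5, "CD45": 3},
}
_TONSIL_LOCS = {
    "naive_t":     {"CD3": 1, "CD10": 1, "CD20": 3, "CD27": 1, "CD38": 1, "CD44": 3, "CD45": 3, "CXCR4": 1},
    "centrocyte":  {"CD3": 1, "CD10": 3, "CD20": 3, "CD27": 1, "CD38": 3, "CD44": 3, "CD45": 3, "CXCR4": 1},
    "centroblast": {"CD3": 1, "CD10": 3, "CD20": 3, "CD27": 1, "CD38": 3, "CD44": 1, "CD45": 3, "CXCR4": 3},
    "memory_t":    {"CD3": 1, "CD10": 1, "CD20": 3, "CD27": 3, "CD38": 1, "CD44": 3, "CD45": 3, "CXCR4": 1},
    "plasmablast": {"CD3": 1, "CD10": 1, "CD20": 1, "CD27": 3, "CD38": 5, "CD44": 1, "CD45": 3, "CXCR4": 1},
}


def default_facs_params() -> dict:
    """(tissue, subset) -> marker -> (lognormal location, scale)."""
    params: dict = {}
    for subset, locs in _BM_LOCS.items():
        params[("bone_marrow", subset)] = {m: (float(v), 0.15) for m, v in locs.items()}
    for subset, locs in _TONSIL_LOCS.items():
        params[("tonsil", subset)] = {m: (float(v), 0.15) for m, v in locs.items()}
    return params


def default_sample_design() -> list[tuple[str, str, str]]:
    """72 arrays: 7 bone-marrow donors x 6 subsets, 6 tonsil donors x 5."""
    design = []
    for d in range(1, 8):
        for subset in SUBSETS_BM:
            design.append(("bone_marrow", subset, f"BM{d}"))
    for d in range(1, 7):
        for subset in SUBSETS_TONSIL:
            design.append(("tonsil", subset, f"T{d}"))
    return design


# Hierarchical developmental contrasts over the eleven subsets, ordered
# (preB1, preB2, immature, naive_bm, memory_bm, plasma_cell | naive_t,
# centrocyte, centroblast, memory_t, plasmablast).  Mutually orthogonal,
# mean zero; block structure makes the implied sample hierarchy decisive:
# tissue first, then developmental stage blocks, then fine stage contrasts.
_PROFILE_BASIS = (
    # tissue program (bone marrow vs tonsil)
    [1, 1, 1, 1, 1, 1, -1.2, -1.2, -1.2, -1.2, -1.2],
    # early B-cell development (precursors vs mature, bone marrow)
    [1, 1, 1, -1, -1, -1, 0, 0, 0, 0, 0],
    # germinal-center program (centrocytes/centroblasts)
    [0, 0, 0, 0, 0, 0, -1, 1.5, 1.5, -1, -1],
    # pre-B vs immature
    [1, 1, -2, 0, 0, 0, 0, 0, 0, 0, 0],
    # terminal plasma-cell differentiation (bone marrow)
    [0, 0, 0, 1, 1, -2, 0, 0, 0, 0, 0],
    # naive-vs-memory axis, with fine pre-B1/pre-B2 and CC/CB contrasts
    [0.4, -0.4, 0, 1, -1, 0, 1, 0.4, -0.4, -1, 0],
    # plasmablast program (tonsil)
    [0, 0, 0, 0, 0, 0, 1, 0, 0, 1, -2],
)


def default_module_profiles(n_modules: int = 7) -> dict[str, dict[str, float]]:
    """Planted per-subset eigengene means for each module.

    The first ``n_modules`` hierarchical developmental contrasts (above),
    each scaled to unit variance across subsets.  Orthogonality keeps the
    planted modules distinct; the nested block structure mimics how real
    B-cell programs partition the subsets (tissue, then stage).
    """
    if n_modules > len(_PROFILE_BASIS):
        raise ValueError(f"at most {len(_PROFILE_BASIS)} default module profiles")
    profiles = {}
    for m in range(n_modules):
        v = np.asarray(_PROFILE_BASIS[m], dtype=float)
        v = (v - v.mean()) / v.std()
        profiles[f"M{m + 1}"] = {s: float(v[i]) for i, s in enumerate(ALL_SUBSETS)}
    return profiles


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults define the standard conditions: ~2000 genes with six biotype
    classes in the proportions of a whole-genome array (scaled down),
    7 planted modules of 120 genes with within-module correlation 0.7,
    planted sense-antisense pairs at r=0.8, and the 72-sample design.
    """

    seed: int = 0
    n_genes_per_biotype: Mapping[str, int] = field(
        default_factory=lambda: {
            "protein_coding": 990,
            "lincRNA": 280,
            "antisense": 210,
            "small_ncRNA": 100,
            "other_lncRNA": 30,
            "pseudogene": 390,
        }
    )
    n_modules: int = 7
    # uneven module sizes (largest first), echoing the skewed size spectrum
    # real co-expression modules show; the dominant module carries the
    # tissue program so the sample hierarchy splits tissue first
    genes_per_module: int | Sequence[int] = (500, 200, 150, 110, 80, 60, 45)
    module_profiles: Mapping[str, Mapping[str, float]] | None = None
    within_module_cor: float = 0.7
    noise_sd: float = 0.65          # gene-level residual, log2 units
    donor_sd: float = 0.2           # additive per-donor offset on eigengenes
    negative_loading_fraction: float = 0.25
    probes_per_gene: tuple[int, int] = (4, 30)
    stale_probe_fraction: float = 0.1
    probe_affinity_sd: float = 0.3
    probe_noise_sd: float = 0.25
    n_background_probes: int = 1000
    bg_base: float = 4.0            # log2 background level at GC 0.5
    bg_gc_slope: float = 2.0        # log2 per unit GC fraction
    bg_noise_sd: float = 0.3
    baseline_range: tuple[float, float] = (6.5, 10.0)
    grey_sd_range: tuple[float, float] = (0.3, 0.9)
    # planted neighbor pairs (counts; antisense pairs split evenly over the
    # three overlap categories)
    n_antisense_pairs: int = 30
    antisense_pair_rho: float = 0.8
    n_linc_mrna_pairs: int = 30
    linc_pair_rho: float = 0.4
    n_mrna_mrna_pairs: int = 30
    mrna_pair_rho: float = 0.25
    n_control_pairs: int = 20       # gap > 1 kb, independent expression
    # designed filter failures
    n_low_expression_genes: int = 30
    n_low_variance_genes: int = 30
    sample_design: Sequence[tuple[str, str, str]] = field(default_factory=default_sample_design)
    facs_params: Mapping = field(default_factory=default_facs_params)
    n_facs_events: int = 10000      # per tissue
    chrom_names: tuple[str, ...] = ("chr1", "chr2")
    chrom_length: int = 60_000_000

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.n_genes_per_biotype.values()):
            raise ValueError("gene counts must be >= 0")
        unknown = set(self.n_genes_per_biotype) - set(BIOTYPES)
        if unknown:
            raise ValueError(f"unknown biotypes: {unknown}")
        if not 0 < self.within_module_cor < 1:
            raise ValueError("within_module_cor must be in (0, 1)")
        if self.n_modules < 1:
            raise ValueError("need at least one module")
        if self.module_profiles is None:
            self.module_profiles = default_module_profiles(self.n_modules)
        if len(self.module_profiles) != self.n_modules:
            raise ValueError("module_profiles must cover n_modules modules")
        if isinstance(self.genes_per_module, int):
            self.genes_per_module = (self.genes_per_module,) * self.n_modules
        else:
            self.genes_per_module = tuple(self.genes_per_module)
        if len(self.genes_per_module) != self.n_modules:
            raise ValueError("genes_per_module must give one size per module")
        if any(s < 2 for s in self.genes_per_module):
            raise ValueError("module sizes must be >= 2")
        if not 0 <= self.stale_probe_fraction <= 1:
            raise ValueError("stale_probe_fraction must be in [0, 1]")
        lo, hi = self.probes_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("invalid probes_per_gene range")
        for tissue, subset, _donor in self.sample_design:
            if subset not in ALL_SUBSETS:
                raise ValueError(f"unknown subset {subset!r} in sample_design")
            if tissue not in ("bone_marrow", "tonsil"):
                raise ValueError(f"unknown tissue {tissue!r} in sample_design")

    @property
    def module_names(self) -> list[str]:
        return list(self.module_profiles)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic substream per generator stage."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """Planted structure behind one simulated study."""

    gene_module: dict[str, str]                 # gene -> "M1".."Mk" or "grey"
    pairs: pd.DataFrame                         # planted neighbor pairs + rho
    filter_fail: pd.DataFrame                   # gene_id, reason
    module_profiles: pd.DataFrame               # modules x subsets
    planted_eigengenes: pd.DataFrame | None = None  # modules x samples

    def module_genes(self, module: str | None = None) -> list[str]:
        if module is None:
            return [g for g, m in self.gene_module.items() if m != "grey"]
        return [g for g, m in self.gene_module.items() if m == module]


# ---------------------------------------------------------------------------
# gene models


def _gene_structure(length: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Relative exon intervals for a gene of the given length.

    Exons >= 200 bp, introns >= 100 bp; first exon starts at 0 and last
    ends at `length`.
    """
    max_exons = min(4, (length - 100) // 300) or 1
    n_ex = int(rng.integers(1, max_exons + 1))
    base = 200 * n_ex + 100 * (n_ex - 1)
    rem = length - base
    extra = rng.multinomial(rem, np.full(2 * n_ex - 1, 1.0 / (2 * n_ex - 1)))
    exons, pos = [], 0
    for i in range(n_ex):
        elen = 200 + int(extra[2 * i])
        exons.append((pos, pos + elen))
        pos += elen
        if i < n_ex - 1:
            pos += 100 + int(extra[2 * i + 1])
    return exons


def generate_gene_models(config: SimulationConfig) -> tuple[GeneModelSet, GroundTruth]:
    """Build the toy genome with planted pair, module, and filter structure."""
    rng = config.rng(1)
    counts = dict(config.n_genes_per_biotype)

    needed_pc = (
        config.n_antisense_pairs
        + config.n_linc_mrna_pairs
        + 2 * config.n_mrna_mrna_pairs
        + 2 * config.n_control_pairs
    )
    if counts.get("protein_coding", 0) < needed_pc:
        raise ValueError("not enough protein_coding genes for the planted pairs")
    if counts.get("antisense", 0) < config.n_antisense_pairs:
        raise ValueError("not enough antisense genes for the planted pairs")
    if counts.get("lincRNA", 0) < config.n_linc_mrna_pairs:
        raise ValueError("not enough lincRNA genes for the planted pairs")

    # roster of gene ids per biotype
    gene_rows: list[dict] = []
    per_biotype: dict[str, list[str]] = {}
    idx = 0
    for bt in BIOTYPES:
        ids = []
        for _ in range(counts.get(bt, 0)):
            idx += 1
            ids.append(f"G{idx:05d}")
        per_biotype[bt] = ids

    def take(bt: str, n: int) -> list[str]:
        out = per_biotype[bt][:n]
        per_biotype[bt] = per_biotype[bt][n:]
        return out

    # --- planted pairs ------------------------------------------------
    pair_rows = []
    units: list[dict] = []  # placement units: singleton gene or pair

    as_categories = ["head_to_head", "tail_to_tail", "fully_overlapping"]
    for i in range(config.n_antisense_pairs):
        a_pc = take("protein_coding", 1)[0]
        b_as = take("antisense", 1)[0]
        cat = as_categories[i % 3]
        pair_rows.append((a_pc, b_as, "antisense_mRNA", cat, config.antisense_pair_rho))
        units.append({"kind": "antisense_pair", "genes": (a_pc, b_as), "cat": cat})
    for _ in range(config.n_linc_mrna_pairs):
        a = take("protein_coding", 1)[0]
        b = take("lincRNA", 1)[0]
        pair_rows.append((a, b, "lincRNA_mRNA", "non_overlapping", config.linc_pair_rho))
        units.append({"kind": "neighbor_pair", "genes": (a, b), "gap": None})
    for _ in range(config.n_mrna_mrna_pairs):
        a, b = take("protein_coding", 2)
        pair_rows.append((a, b, "mRNA_mRNA", "non_overlapping", config.mrna_pair_rho))
        units.append({"kind": "neighbor_pair", "genes": (a, b), "gap": None})
    for _ in range(config.n_control_pairs):
        a, b = take("protein_coding", 2)
        pair_rows.append((a, b, "control", "non_overlapping", 0.0))
        units.append({"kind": "distal_pair", "genes": (a, b)})

    # remaining genes placed as singletons
    singles: list[tuple[str, str]] = []
    for bt in BIOTYPES:
        singles.extend((g, bt) for g in per_biotype[bt])
    for g, _bt in singles:
        units.append({"kind": "single", "genes": (g,)})

    # biotype map follows the allocation order above
    biotype_of = {}
    idx = 0
    for bt in BIOTYPES:
        for _ in range(counts.get(bt, 0)):
            idx += 1
            biotype_of[f"G{idx:05d}"] = bt

    # --- module / filter-fail designation (disjoint, from non-pair genes).
    # Modules draw genes from every biotype class in proportion to its
    # abundance, echoing the mixed composition of real co-expression
    # modules; the biotype-stratified allocation also means protein-coding
    # and lncRNA views of a module carry the same planted signal mix.
    free_by_bt = {bt: list(per_biotype[bt]) for bt in BIOTYPES}
    for bt in BIOTYPES:
        rng.shuffle(free_by_bt[bt])
    n_free = sum(len(v) for v in free_by_bt.values())
    n_module_genes = sum(config.genes_per_module)
    n_fail = config.n_low_expression_genes + config.n_low_variance_genes
    if n_free < n_module_genes + n_fail:
        raise ValueError(
            "not enough genes for the requested module and filter-fail design"
        )
    gene_module: dict[str, str] = {}
    for m, size in zip(config.module_names, config.genes_per_module):
        picked: list[str] = []
        fracs = {bt: len(free_by_bt[bt]) for bt in BIOTYPES}
        total = sum(fracs.values())
        for bt in BIOTYPES:
            take_n = int(round(size * fracs[bt] / total))
            picked.extend(free_by_bt[bt][:take_n])
            free_by_bt[bt] = free_by_bt[bt][take_n:]
        # integer rounding: top up / trim from the largest pools
        while len(picked) < size:
            bt = max(BIOTYPES, key=lambda b: len(free_by_bt[b]))
            picked.append(free_by_bt[bt].pop(0))
        for g in picked[:size]:
            gene_module[g] = m
        for g in picked[size:]:
            free_by_bt[biotype_of[g]].append(g)
    free = [g for bt in BIOTYPES for g in free_by_bt[bt]]
    rng.shuffle(free)
    fail_rows = []
    for g in free[: config.n_low_expression_genes]:
        fail_rows.append((g, "low_expression"))
    for g in free[
        config.n_low_expression_genes : config.n_low_expression_genes
        + config.n_low_variance_genes
    ]:
        fail_rows.append((g, "low_variance"))

    # --- genome placement ---------------------------------------------
    genes_out, tx_out, ex_out = [], [], []

    def emit_gene(gene_id: str, chrom: str, start: int, length: int, strand: str):
        exon_rel = _gene_structure(length, rng)
        genes_out.append(
            (gene_id, chrom, start, start + length, strand, biotype_of[gene_id])
        )
        n_tx = 1 if rng.random() < 0.7 or len(exon_rel) == 1 else 2
        for t in range(1, n_tx + 1):
            tx_id = f"{gene_id}.t{t}"
            tx_out.append((tx_id, gene_id))
            # second transcript uses a prefix of the exons, so the exon
            # union over transcripts equals transcript 1's exons
            use = exon_rel if t == 1 else exon_rel[: len(exon_rel) - 1]
            for s, e in use:
                ex_out.append((tx_id, chrom, start + s, start + e, strand))

    order = rng.permutation(len(units))
    cursors = {c: 10_000 for c in config.chrom_names}
    for j, ui in enumerate(order):
        unit = units[ui]
        chrom = config.chrom_names[j % len(config.chrom_names)]
        pos = cursors[chrom] + int(rng.integers(2000, 10001))
        if unit["kind"] == "single":
            length = int(rng.integers(2000, 10001))
            strand = "+" if rng.random() < 0.5 else "-"
            emit_gene(unit["genes"][0], chrom, pos, length, strand)
            end = pos + length
        elif unit["kind"] == "antisense_pair":
            a, b = unit["genes"]
            if unit["cat"] == "fully_overlapping":
                la = int(rng.integers(4000, 10001))
                lb = int(rng.integers(1000, la - 400 + 1))
                emit_gene(a, chrom, pos, la, "+")
                emit_gene(b, chrom, pos + 200, lb, "-")
                end = pos + la
            else:
                la = int(rng.integers(2000, 6001))
                lb = int(rng.integers(2000, 6001))
                ov = int(rng.integers(300, min(la, lb) - 300 + 1))
                if unit["cat"] == "head_to_head":
                    # antisense 5' (its right end) inside the sense 5' region
                    b_start = pos + ov - lb
                    emit_gene(b, chrom, b_start, lb, "-")
                    emit_gene(a, chrom, pos, la, "+")
                    end = pos + la
                else:  # tail_to_tail: 3' ends overlap
                    b_start = pos + la - ov
                    emit_gene(a, chrom, pos, la, "+")
                    emit_gene(b, chrom, b_start, lb, "-")
                    end = b_start + lb
        elif unit["kind"] == "neighbor_pair":
            la = int(rng.integers(2000, 8001))
            lb = int(rng.integers(2000, 8001))
            gap = int(rng.integers(50, 951))
            sa = "+" if rng.random() < 0.5 else "-"
            sb = "+" if rng.random() < 0.5 else "-"
            a, b = unit["genes"]
            emit_gene(a, chrom, pos, la, sa)
            emit_gene(b, chrom, pos + la + gap, lb, sb)
            end = pos + la + gap + lb
        else:  # distal_pair, gap > 1 kb
            la = int(rng.integers(2000, 8001))
            lb = int(rng.integers(2000, 8001))
            gap = int(rng.integers(1200, 1801))
            a, b = unit["genes"]
            emit_gene(a, chrom, pos, la, "+")
            emit_gene(b, chrom, pos + la + gap, lb, "+")
            end = pos + la + gap + lb
        if end > config.chrom_length:
            raise ValueError(
                f"chromosome {chrom} too short ({config.chrom_length} bp) for the "
                "requested genes; increase chrom_length"
            )
        cursors[chrom] = end

    gene_models = GeneModelSet(
        pd.DataFrame(
            genes_out, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"]
        ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True),
        pd.DataFrame(tx_out, columns=["transcript_id", "gene_id"]),
        pd.DataFrame(ex_out, columns=["transcript_id", "chrom", "start", "end", "strand"]),
    )
    for g in gene_models.gene_ids:
        gene_module.setdefault(g, "grey")
    fail_df = pd.DataFrame(fail_rows, columns=["gene_id", "reason"])
    assert not set(fail_df["gene_id"]) & {
        g for g, m in gene_module.items() if m != "grey"
    }, "filter-fail genes must not carry module structure"
    truth = GroundTruth(
        gene_module=gene_module,
        pairs=pd.DataFrame(
            pair_rows, columns=["gene_a", "gene_b", "pair_class", "overlap_class", "rho"]
        ),
        filter_fail=fail_df,
        module_profiles=pd.DataFrame(config.module_profiles).T[list(ALL_SUBSETS)],
    )
    return gene_models, truth


# ---------------------------------------------------------------------------
# probes


def generate_probes(gene_models: GeneModelSet, config: SimulationConfig) -> pd.DataFrame:
    """Probe table: exon-contained gene probes, stale probes, background probes.

    Columns: probe_id, chrom, start, end, strand, gc_fraction, is_background,
    source_gene.  ``source_gene`` records which transcript a probe measures
    (ground truth for the intensity simulation); the remapping stage never
    reads it.
    """
    rng = config.rng(2)
    lo, hi = config.probes_per_gene
    rows = []
    ex_by_gene = gene_models.exons_by_gene()
    pid = 0
    for g in gene_models.genes.itertuples(index=False):
        gx = ex_by_gene[ex_by_gene["gene_id"] == g.gene_id]
        # exon union = transcript 1's exons by construction
        exons = sorted(
            {(int(s), int(e)) for s, e in zip(gx["start"], gx["end"])}
        )
        n_probes = int(rng.integers(lo, hi + 1))
        for _ in range(n_probes):
            pid += 1
            stale = rng.random() < config.stale_probe_fraction
            if stale:
                # straddle an exon boundary: 12 bases in, the rest outside
                s_ex, e_ex = exons[int(rng.integers(len(exons)))]
                start = e_ex - 12
            else:
                k = int(rng.integers(len(exons)))
                s_ex, e_ex = exons[k]
                start = int(rng.integers(s_ex, e_ex - PROBE_LENGTH + 1))
            rows.append(
                (
                    f"P{pid:06d}",
                    g.chrom,
                    start,
                    start + PROBE_LENGTH,
                    g.strand,
                    round(float(rng.uniform(0.25, 0.75)), 3),
                    False,
                    g.gene_id,
                )
            )
    for _ in range(config.n_background_probes):
        pid += 1
        rows.append(
            (
                f"P{pid:06d}",
                "antigenomic",
                0,
                PROBE_LENGTH,
                "+",
                round(float(rng.uniform(0.15, 0.85)), 3),
                True,
                "",
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "probe_id", "chrom", "start", "end", "strand",
            "gc_fraction", "is_background", "source_gene",
        ],
    )


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    gene_models: GeneModelSet,
    ground_truth: GroundTruth,
    probes: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probe-level linear intensities plus sample metadata.

    Latent factor model: eigengene value e_m(s) = planted profile of module m
    at subset(s) plus a per-donor offset; member gene log2 value = baseline
    + sign * loading * e_m(s) + noise, with the loading calibrated so the
    mean within-module pairwise correlation matches ``within_module_cor``.
    Probe intensity = gene value + probe affinity + probe noise, exponentiated
    to the linear scale; background probes follow a GC-dependent baseline.
    """
    if not len(config.sample_design):
        raise ValueError("sample_design is empty")
    rng = config.rng(3)
    design = pd.DataFrame(config.sample_design, columns=["tissue", "subset", "donor"])
    design["sample_id"] = [
        f"{t}_{d}_{s}" for t, s, d in zip(design["tissue"], design["subset"], design["donor"])
    ]
    n_samples = len(design)
    modules = config.module_names
    donors = sorted(set(design["donor"]))

    # eigengenes: profile + donor offset
    prof = ground_truth.module_profiles
    donor_offsets = {
        (m, d): rng.normal(0.0, config.donor_sd) for m in modules for d in donors
    }
    eig = np.zeros((len(modules), n_samples))
    for j, row in enumerate(design.itertuples(index=False)):
        for i, m in enumerate(modules):
            eig[i, j] = prof.loc[m, row.subset] + donor_offsets[(m, row.donor)]
    eig_df = pd.DataFrame(eig, index=modules, columns=design["sample_id"])
    ground_truth.planted_eigengenes = eig_df

    wc = config.within_module_cor
    # loading so that loading^2 var(e) / (loading^2 var(e) + noise^2) = wc
    loadings = {
        m: config.noise_sd * np.sqrt(wc / (1 - wc)) / max(eig[i].std(), 1e-12)
        for i, m in enumerate(modules)
    }

    gene_ids = gene_models.gene_ids
    fail_reason = dict(
        zip(ground_truth.filter_fail["gene_id"], ground_truth.filter_fail["reason"])
    )
    pair_lookup: dict[str, tuple[int, int, float]] = {}
    for k, row in enumerate(ground_truth.pairs.itertuples(index=False)):
        if row.rho > 0:
            pair_lookup[row.gene_a] = (k, 0, row.rho)
            pair_lookup[row.gene_b] = (k, 1, row.rho)
    # shared + independent factors for planted pairs
    z_shared = rng.normal(size=(len(ground_truth.pairs), n_samples))
    z_indep = rng.normal(size=(len(ground_truth.pairs), 2, n_samples))

    gene_log2 = np.zeros((len(gene_ids), n_samples))
    for i, g in enumerate(gene_ids):
        baseline = rng.uniform(*config.baseline_range)
        reason = fail_reason.get(g)
        module = ground_truth.gene_module.get(g, "grey")
        if reason == "low_expression":
            gene_log2[i] = 3.0 + rng.normal(0.0, 0.3, n_samples)
        elif reason == "low_variance":
            gene_log2[i] = baseline + rng.normal(0.0, 0.15, n_samples)
        elif g in pair_lookup:
            k, side, rho = pair_lookup[g]
            signal = np.sqrt(rho) * z_shared[k] + np.sqrt(1 - rho) * z_indep[k, side]
            gene_log2[i] = baseline + signal
        elif module != "grey":
            sign = -1.0 if rng.random() < config.negative_loading_fraction else 1.0
            m_idx = modules.index(module)
            gene_log2[i] = (
                baseline
                + sign * loadings[module] * eig[m_idx]
                + rng.normal(0.0, config.noise_sd, n_samples)
            )
        else:
            sd = rng.uniform(*config.grey_sd_range)
            gene_log2[i] = baseline + rng.normal(0.0, sd, n_samples)

    gene_index = {g: i for i, g in enumerate(gene_ids)}
    probe_log2 = np.zeros((len(probes), n_samples))
    gc = probes["gc_fraction"].to_numpy()
    is_bg = probes["is_background"].to_numpy()
    for p, row in enumerate(probes.itertuples(index=False)):
        if row.is_background:
            probe_log2[p] = (
                config.bg_base
                + config.bg_gc_slope * (gc[p] - 0.5)
                + rng.normal(0.0, config.bg_noise_sd, n_samples)
            )
        else:
            affinity = rng.normal(0.0, config.probe_affinity_sd)
            probe_log2[p] = (
                gene_log2[gene_index[row.source_gene]]
                + affinity
                + rng.normal(0.0, config.probe_noise_sd, n_samples)
            )
    intensities = pd.DataFrame(
        np.exp2(probe_log2), index=probes["probe_id"].to_numpy(), columns=design["sample_id"]
    )
    metadata = design[["sample_id", "tissue", "subset", "donor"]]
    _ = is_bg  # documented column; background handled above
    return intensities, metadata


# ---------------------------------------------------------------------------
# coding potential and GO annotation


def generate_coding_potential(
    gene_models: GeneModelSet, config: SimulationConfig
) -> pd.DataFrame:
    """Per-transcript coding probabilities: high for protein-coding genes,
    low for noncoding classes (CPAT-style output)."""
    rng = config.rng(4)
    bt = gene_models.biotype_map()
    rows = []
    for tx in gene_models.transcripts.itertuples(index=False):
        coding = bt[tx.gene_id] == "protein_coding"
        p = rng.beta(6.0, 1.5) if coding else rng.beta(1.2, 6.0)
        rows.append((tx.transcript_id, tx.gene_id, round(float(p), 6)))
    return pd.DataFrame(rows, columns=["transcript_id", "gene_id", "coding_prob"])


def generate_go_annotations(
    gene_models: GeneModelSet, ground_truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Two-column (term_id, gene_id) annotation with planted module terms.

    Each module gets three terms annotating ~40% of its genes (plus a 1%
    background rate elsewhere), so overrepresentation analysis has signal
    to find; 15 additional unenriched terms annotate random genes.
    """
    rng = config.rng(5)
    genes = np.array(gene_models.gene_ids)
    rows = []
    term_no = 0
    for m in config.module_names:
        members = np.array(ground_truth.module_genes(m))
        for _ in range(3):
            term_no += 1
            term = f"GO:{term_no:07d}"
            if len(members):
                picked = members[rng.random(len(members)) < 0.4]
                rows.extend((term, g) for g in picked)
            bg = genes[rng.random(len(genes)) < 0.01]
            rows.extend((term, g) for g in bg if ground_truth.gene_module.get(g) != m)
    for _ in range(15):
        term_no += 1
        term = f"GO:{term_no:07d}"
        picked = genes[rng.random(len(genes)) < 0.05]
        rows.extend((term, g) for g in picked)
    df = pd.DataFrame(rows, columns=["term_id", "gene_id"]).drop_duplicates()
    return df.sort_values(["term_id", "gene_id"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# FACS


def simulate_facs(
    config: SimulationConfig, tissue: str, n_events: int | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Labelled flow-cytometry events for one tissue.

    Events are split evenly over the tissue's subsets; each marker value is
    lognormal with the subset-specific (location, scale) from
    ``config.facs_params``.
    """
    rng = config.rng(6 if tissue == "bone_marrow" else 7)
    if tissue == "bone_marrow":
        subsets, markers = SUBSETS_BM, BM_MARKERS
    elif tissue == "tonsil":
        subsets, markers = SUBSETS_TONSIL, TONSIL_MARKERS
    else:
        raise ValueError(f"unknown tissue {tissue!r}")
    n_events = config.n_facs_events if n_events is None else n_events
    # balanced design: equal events per sorted population (remainder dropped)
    per = n_events // len(subsets)
    counts = [per] * len(subsets)
    frames = []
    for subset, n in zip(subsets, counts):
        key = (tissue, subset)
        if key not in config.facs_params:
            raise ValueError(f"missing FACS parameters for {key}")
        params = config.facs_params[key]
        missing = [m for m in markers if m not in params]
        if missing:
            raise ValueError(f"missing marker parameters for {key}: {missing}")
        cols = {
            m: rng.lognormal(params[m][0], params[m][1], n) for m in markers
        }
        df = pd.DataFrame(cols)
        df.insert(0, "tissue", tissue)
        df["subset"] = subset
        frames.append(df)
    if not frames or n_events == 0:
        empty = pd.DataFrame(columns=["tissue", *markers])
        return empty, pd.Series([], dtype=object, name="subset")
    events = pd.concat(frames, ignore_index=True)
    labels = events.pop("subset")
    labels.name = "subset"
    return events, labels


# ---------------------------------------------------------------------------
# one-call generation + writers


def simulate_study(config: SimulationConfig) -> dict:
    """Generate every pipeline input in memory; returns a dict of artifacts."""
    gene_models, truth = generate_gene_models(config)
    probes = generate_probes(gene_models, config)
    intensities, metadata = simulate_expression(gene_models, truth, probes, config)
    coding = generate_coding_potential(gene_models, config)
    go = generate_go_annotations(gene_models, truth, config)
    facs = {}
    for tissue in ("bone_marrow", "tonsil"):
        events, labels = simulate_facs(config, tissue)
        facs[tissue] = (events, labels)
    return {
        "config": config,
        "gene_models": gene_models,
        "ground_truth": truth,
        "probes": probes,
        "intensities": intensities,
        "metadata": metadata,
        "coding": coding,
        "go": go,
        "facs": facs,
    }


def write_study(study: dict, outdir: str | Path) -> dict[str, Path]:
    """Write all generated inputs as plain-text files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_models": outdir / "gene_models.gtf",
        "probes": outdir / "probes.tsv",
        "intensities": outdir / "probe_intensities.tsv",
        "metadata": outdir / "sample_metadata.tsv",
        "coding": outdir / "coding_probabilities.tsv",
        "go": outdir / "go_annotations.tsv",
    }
    write_gtf(study["gene_models"], paths["gene_models"])
    write_tsv(study["probes"].drop(columns=["source_gene"]), paths["probes"])
    write_matrix_tsv(study["intensities"], paths["intensities"])
    write_tsv(study["metadata"], paths["metadata"])
    write_tsv(study["coding"], paths["coding"])
    write_tsv(study["go"], paths["go"])
    for tissue, (events, labels) in study["facs"].items():
        p = outdir / f"facs_{tissue}.csv"
        out = events.copy()
        out["subset"] = labels.to_numpy() if len(labels) else []
        out.to_csv(p, index=False, float_format="%.6g")
        paths[f"facs_{tissue}"] = p
    truth_df = pd.DataFrame(
        {"gene_id": list(study["ground_truth"].gene_module),
         "module": list(study["ground_truth"].gene_module.values())}
    )
    paths["truth_modules"] = outdir / "truth_modules.tsv"
    write_tsv(truth_df, paths["truth_modules"])
    return paths
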