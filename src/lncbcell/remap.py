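"""Gene-level probe-set construction against current gene models.

Array probes designed against older annotation are re-assigned to genes:
a probe belongs to a gene only if it is fully contained in an exon of at
least one of the gene's transcripts, on the same strand.  Probes matching
no gene, or more than one, are discarded; small resulting probe sets are
excluded before summarization.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .io import read_gtf  # re-exported reader; GTF handling lives in io
from .models import GeneModelSet, ProbeSetMap

__all__ = ["read_gene_models", "assign_probes", "filter_probe_sets", "FilterReport"]

read_gene_models = read_gtf


def assign_probes(probes: pd.DataFrame, gene_models: GeneModelSet) -> ProbeSetMap:
    """Assign probes to genes by strand-matched exon containment.

    Status per probe: ``assigned`` (contained in >=1 exon of exactly one
    gene), ``not_contained``, ``ambiguous`` (contained in exons of >=2
    genes; dropped), or ``background`` (probes flagged is_background).

    Raises if a non-background probe names a chromosome absent from the
    gene models.
    """
    ex = gene_models.exons_by_gene()
    trees: dict[tuple[str, str], IntervalTree] = {}
    for key, sub in ex.groupby(["chrom", "strand"], sort=False):
        trees[key] = IntervalTree.from_tuples(
            (int(s), int(e), g)
            for s, e, g in zip(sub["start"], sub["end"], sub["gene_id"])
        )
    known_chroms = set(gene_models.genes["chrom"])

    has_bg = "is_background" in probes.columns
    genomic = probes.loc[~probes["is_background"]] if has_bg else probes
    unknown = sorted(set(genomic["chrom"]) - known_chroms)
    if unknown:
        raise ValueError(f"probes on chromosomes absent from gene models: {unknown}")

    gene_to_probes: dict[str, list[str]] = {}
    status: dict[str, str] = {}
    for row in probes.itertuples(index=False):
        if has_bg and row.is_background:
            status[row.probe_id] = "background"
            continue
        tree = trees.get((row.chrom, row.strand))
        hits = set()
        if tree is not None:
            for iv in tree.overlap(row.start, row.end):
                if iv.begin <= row.start and row.end <= iv.end:
                    hits.add(iv.data)
        if not hits:
            status[row.probe_id] = "not_contained"
        elif len(hits) > 1:
            status[row.probe_id] = "ambiguous"
        else:
            status[row.probe_id] = "assigned"
            gene_to_probes.setdefault(hits.pop(), []).append(row.probe_id)
    return ProbeSetMap(gene_to_probes, status)


@dataclass
class FilterReport:
    min_probes: int
    removed_genes: list[str]
    retained_genes: int


def filter_probe_sets(
    probe_map: ProbeSetMap, min_probes: int = 4
) -> tuple[ProbeSetMap, FilterReport]:
    """Drop genes whose probe set has fewer than ``min_probes`` probes.

    The default of 4 excludes probe sets of 1-3 probes, which are too
    small to summarize reliably.
    """
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    kept = {g: p for g, p in probe_map.gene_to_probes.items() if len(p) >= min_probes}
    removed = sorted(set(probe_map.gene_to_probes) - set(kept))
    return (
        ProbeSetMap(kept, dict(probe_map.status)),
        FilterReport(min_probes=min_probes, removed_genes=removed, retained_genes=len(kept)),
    )
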