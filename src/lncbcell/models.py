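"""Core in-memory containers shared across the pipeline.

Coordinate convention: every interval held in memory is 0-based,
half-open ``[start, end)``.  GTF input/output converts to and from the
1-based inclusive convention of that format at the file boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: The six Ensembl-derived biotype classes used throughout the analysis.
BIOTYPES = (
    "protein_coding",
    "lincRNA",
    "antisense",
    "small_ncRNA",
    "other_lncRNA",
    "pseudogene",
)

#: Biotypes collectively treated as long noncoding for class-level analyses.
LNCRNA_CLASSES = ("lincRNA", "antisense", "small_ncRNA", "other_lncRNA", "pseudogene")

#: The eleven sorted B-cell populations (bone marrow, then tonsil).
SUBSETS_BM = ("preB1", "preB2", "immature", "naive_bm", "memory_bm", "plasma_cell")
SUBSETS_TONSIL = ("naive_t", "centrocyte", "centroblast", "memory_t", "plasmablast")
ALL_SUBSETS = SUBSETS_BM + SUBSETS_TONSIL


@dataclass
class GeneModelSet:
    """Gene models: genes, their transcripts and per-transcript exons.

    Attributes
    ----------
    genes : DataFrame with columns gene_id, chrom, start, end, strand, biotype
    transcripts : DataFrame with columns transcript_id, gene_id
    exons : DataFrame with columns transcript_id, chrom, start, end, strand
    """

    genes: pd.DataFrame
    transcripts: pd.DataFrame
    exons: pd.DataFrame

    def __post_init__(self) -> None:
        g = self.genes
        if g["gene_id"].duplicated().any():
            dups = g.loc[g["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        bad = set(g["strand"]) - {"+", "-"}
        if bad:
            raise ValueError(f"invalid strand values: {bad}")
        if (g["end"] <= g["start"]).any():
            raise ValueError("gene with end <= start")
        if len(self.exons) and (self.exons["end"] <= self.exons["start"]).any():
            raise ValueError("exon with end <= start")
        # every exon must fall inside its gene's span
        tx2gene = dict(zip(self.transcripts["transcript_id"], self.transcripts["gene_id"]))
        span = g.set_index("gene_id")[["start", "end"]]
        ex_gene = self.exons["transcript_id"].map(tx2gene)
        gs = span["start"].reindex(ex_gene).to_numpy()
        ge = span["end"].reindex(ex_gene).to_numpy()
        if len(self.exons) and (
            (self.exons["start"].to_numpy() < gs) | (self.exons["end"].to_numpy() > ge)
        ).any():
            raise ValueError("exon outside its gene span")

    @property
    def gene_ids(self) -> list[str]:
        return self.genes["gene_id"].tolist()

    def biotype_map(self) -> pd.Series:
        return self.genes.set_index("gene_id")["biotype"]

    def exons_by_gene(self) -> pd.DataFrame:
        """Exons joined with their gene id (one row per transcript exon)."""
        tx2gene = self.transcripts.set_index("transcript_id")["gene_id"]
        out = self.exons.copy()
        out["gene_id"] = out["transcript_id"].map(tx2gene)
        return out


@dataclass
class ProbeSetMap:
    """Gene-level probe sets plus per-probe assignment status.

    ``status`` maps every input probe to exactly one of
    {assigned, not_contained, ambiguous, background}.
    """

    gene_to_probes: dict[str, list[str]]
    status: dict[str, str]

    def counts(self) -> dict[str, int]:
        out = {"assigned": 0, "not_contained": 0, "ambiguous": 0, "background": 0}
        for s in self.status.values():
            out[s] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, p) for g, probes in sorted(self.gene_to_probes.items()) for p in probes
        ]
        return pd.DataFrame(rows, columns=["gene_id", "probe_id"])


@dataclass
class ExpressionMatrix:
    """Gene-level log2 expression with sample metadata.

    values: genes x samples; metadata indexed like the columns with
    sample_id, tissue, subset, donor.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        meta_ids = set(self.metadata["sample_id"])
        missing = [c for c in self.values.columns if c not in meta_ids]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:5]}")

    def subset_of(self, sample_id: str) -> str:
        row = self.metadata.loc[self.metadata["sample_id"] == sample_id]
        return str(row["subset"].iloc[0])

    def select_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.metadata)
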