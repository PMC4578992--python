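"""File-format boundary: GTF gene models and the TSV/CSV tables.

GTF is written/read in its native 1-based inclusive coordinates and
converted to the package-internal 0-based half-open convention on read.
The reader is deliberately strict — a malformed record fails loudly with
its line number rather than being skipped.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import pandas as pd

from .models import GeneModelSet


class GtfParseError(ValueError):
    def __init__(self, lineno: int, message: str):
        super().__init__(f"GTF line {lineno}: {message}")
        self.lineno = lineno


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path: str | Path) -> GeneModelSet:
    """Read gene/transcript/exon features with gene_biotype attributes.

    Genes that carry no exon on any transcript are rejected (dropped with
    a warning) since they cannot anchor probes.
    """
    genes, transcripts, exons = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(lineno, f"expected 9 fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(lineno, "non-integer coordinates") from None
            if end1 < start1:
                raise GtfParseError(lineno, f"end {end1} < start {start1}")
            if strand not in "+-":
                raise GtfParseError(lineno, f"invalid strand {strand!r}")
            start, end = start1 - 1, end1  # to 0-based half-open
            a = _parse_attributes(attrs)
            if "gene_id" not in a:
                raise GtfParseError(lineno, "missing gene_id attribute")
            if feature == "gene":
                genes.append(
                    (a["gene_id"], chrom, start, end, strand, a.get("gene_biotype", ""))
                )
            elif feature == "transcript":
                if "transcript_id" not in a:
                    raise GtfParseError(lineno, "transcript without transcript_id")
                transcripts.append((a["transcript_id"], a["gene_id"]))
            elif feature == "exon":
                if "transcript_id" not in a:
                    raise GtfParseError(lineno, "exon without transcript_id")
                exons.append((a["transcript_id"], chrom, start, end, strand))
            # other feature types (CDS, UTR, ...) are ignored

    genes_df = pd.DataFrame(
        genes, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"]
    )
    tx_df = pd.DataFrame(transcripts, columns=["transcript_id", "gene_id"])
    ex_df = pd.DataFrame(exons, columns=["transcript_id", "chrom", "start", "end", "strand"])

    tx_with_exons = set(ex_df["transcript_id"])
    genes_with_exons = set(tx_df.loc[tx_df["transcript_id"].isin(tx_with_exons), "gene_id"])
    orphan = genes_df.loc[~genes_df["gene_id"].isin(genes_with_exons), "gene_id"]
    if len(orphan):
        warnings.warn(
            f"rejected {len(orphan)} gene(s) without exons: {orphan.tolist()[:5]}",
            stacklevel=2,
        )
        genes_df = genes_df[genes_df["gene_id"].isin(genes_with_exons)].reset_index(drop=True)
        tx_df = tx_df[tx_df["gene_id"].isin(genes_with_exons)].reset_index(drop=True)
        ex_df = ex_df[ex_df["transcript_id"].isin(set(tx_df["transcript_id"]))].reset_index(
            drop=True
        )
    return GeneModelSet(genes_df, tx_df, ex_df)


def write_gtf(gene_models: GeneModelSet, path: str | Path, source: str = "lncbcell") -> None:
    """Write gene/transcript/exon records, 1-based inclusive coordinates."""
    tx_by_gene: dict[str, list[str]] = {}
    for tx_id, gene_id in zip(
        gene_models.transcripts["transcript_id"], gene_models.transcripts["gene_id"]
    ):
        tx_by_gene.setdefault(gene_id, []).append(tx_id)
    ex_by_tx: dict[str, list[tuple]] = {}
    for row in gene_models.exons.itertuples(index=False):
        ex_by_tx.setdefault(row.transcript_id, []).append(row)

    with open(path, "w") as fh:
        for g in gene_models.genes.itertuples(index=False):
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for tx_id in tx_by_gene.get(g.gene_id, []):
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{tx_id}"; gene_biotype "{g.biotype}";'
                ex = sorted(ex_by_tx.get(tx_id, []), key=lambda r: r.start)
                if ex:
                    t_start, t_end = ex[0].start, max(r.end for r in ex)
                else:
                    t_start, t_end = g.start, g.end
                fh.write(
                    f"{g.chrom}\t{source}\ttranscript\t{t_start + 1}\t{t_end}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for r in ex:
                    fh.write(
                        f"{r.chrom}\t{source}\texon\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\t{tattrs}\n"
                    )


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="id", float_format="%.10g")


def read_probe_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
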