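"""Biotype-aware annotation: per-gene coding-potential summaries and the
catalogue of genomic neighbor pairs (within 1 kb) with their co-expression.

Sense-antisense overlap is classified by which stranded ends overlap:
head-to-head (5' ends), tail-to-tail (3' ends), or fully overlapping (one
gene embedded in the other); all geometry is on gene spans, with exon
overlap recorded as an extra flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import ExpressionMatrix, GeneModelSet

PAIR_CLASSES = ("antisense_mRNA", "lincRNA_mRNA", "mRNA_mRNA", "other")


def summarize_coding_potential(transcript_probs: pd.DataFrame) -> pd.DataFrame:
    """Per-gene transcript count, mean, max and range of coding probability.

    Input columns: gene_id, coding_prob (one row per transcript).
    """
    if len(transcript_probs) == 0:
        return pd.DataFrame(
            columns=["gene_id", "n_transcripts", "cpat_mean", "cpat_max", "cpat_range"]
        )
    p = transcript_probs["coding_prob"]
    if ((p < 0) | (p > 1)).any():
        raise ValueError("coding probabilities must lie in [0, 1]")
    g = transcript_probs.groupby("gene_id")["coding_prob"]
    out = pd.DataFrame(
        {
            "n_transcripts": g.size(),
            "cpat_mean": g.mean(),
            "cpat_max": g.max(),
            "cpat_range": g.max() - g.min(),
        }
    ).reset_index()
    return out


def _five_prime(start: int, end: int, strand: str) -> int:
    return start if strand == "+" else end


def _three_prime(start: int, end: int, strand: str) -> int:
    return end if strand == "+" else start


def _overlap_class(a, b) -> str:
    """Classify span geometry of two genes known to overlap."""
    if (a.start <= b.start and b.end <= a.end) or (b.start <= a.start and a.end <= b.end):
        return "fully_overlapping"
    if a.strand == b.strand:
        return "partial_other"
    lo, hi = max(a.start, b.start), min(a.end, b.end)
    fp_a, fp_b = _five_prime(a.start, a.end, a.strand), _five_prime(b.start, b.end, b.strand)
    tp_a, tp_b = _three_prime(a.start, a.end, a.strand), _three_prime(b.start, b.end, b.strand)
    if lo <= fp_a <= hi and lo <= fp_b <= hi:
        return "head_to_head"
    if lo <= tp_a <= hi and lo <= tp_b <= hi:
        return "tail_to_tail"
    return "partial_other"


def _pair_class(bt_a: str, bt_b: str) -> str:
    pair = {bt_a, bt_b}
    if pair == {"antisense", "protein_coding"}:
        return "antisense_mRNA"
    if pair == {"lincRNA", "protein_coding"}:
        return "lincRNA_mRNA"
    if pair == {"protein_coding"}:
        return "mRNA_mRNA"
    return "other"


def find_local_pairs(gene_models: GeneModelSet, max_gap: int = 1000) -> pd.DataFrame:
    """All unordered same-chromosome gene pairs with span gap <= max_gap.

    Overlapping genes count as gap 0.  Each pair is annotated with strand
    relation, overlap class, exon overlap, and a biotype-derived class.
    """
    genes = gene_models.genes.sort_values(["chrom", "start"], kind="stable")
    ex = gene_models.exons_by_gene()
    exons_of = {
        g: list(zip(sub["start"], sub["end"]))
        for g, sub in ex.groupby("gene_id", sort=False)
    }

    def exons_overlap(ga: str, gb: str) -> bool:
        for s1, e1 in exons_of.get(ga, ()):  # pragma: no branch
            for s2, e2 in exons_of.get(gb, ()):
                if max(s1, s2) < min(e1, e2):
                    return True
        return False

    rows = []
    for _, sub in genes.groupby("chrom", sort=False):
        recs = list(sub.itertuples(index=False))
        for i, a in enumerate(recs):
            for b in recs[i + 1 :]:
                if b.start > a.end + max_gap:
                    # starts are sorted, so every later b is even further
                    break
                gap = max(0, max(a.start, b.start) - min(a.end, b.end))
                if gap > max_gap:
                    continue
                overlap = max(a.start, b.start) < min(a.end, b.end)
                rows.append(
                    {
                        "gene_a": a.gene_id,
                        "gene_b": b.gene_id,
                        "chrom": a.chrom,
                        "gap_bp": gap,
                        "strand_relation": "same" if a.strand == b.strand else "opposite",
                        "overlap_class": _overlap_class(a, b) if overlap else "non_overlapping",
                        "exon_overlap": exons_overlap(a.gene_id, b.gene_id) if overlap else False,
                        "pair_class": _pair_class(a.biotype, b.biotype),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_a", "gene_b", "chrom", "gap_bp", "strand_relation",
            "overlap_class", "exon_overlap", "pair_class",
        ],
    )


def pair_coexpression(
    pairs: pd.DataFrame, expr: ExpressionMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation over samples for every pair with both genes in expr.

    Returns the annotated pair table (column ``correlation``; NaN and
    ``flagged=True`` for zero-variance members) and a per-class summary
    (n pairs, mean r, median r) over unflagged pairs.  Pairs with a
    filtered-out member are dropped and counted in the summary's
    ``n_dropped`` attribute column.
    """
    values = expr.values
    have = set(values.index)
    keep = pairs["gene_a"].isin(have) & pairs["gene_b"].isin(have)
    dropped = int((~keep).sum())
    out = pairs.loc[keep].copy()
    x = values.to_numpy()
    idx = {g: i for i, g in enumerate(values.index)}
    sd = x.std(axis=1, ddof=1)
    xc = x - x.mean(axis=1, keepdims=True)
    corrs, flags = [], []
    for ga, gb in zip(out["gene_a"], out["gene_b"]):
        ia, ib = idx[ga], idx[gb]
        if sd[ia] == 0 or sd[ib] == 0:
            corrs.append(np.nan)
            flags.append(True)
        else:
            r = float(np.dot(xc[ia], xc[ib]) / (np.linalg.norm(xc[ia]) * np.linalg.norm(xc[ib])))
            corrs.append(r)
            flags.append(False)
    out["correlation"] = np.array(corrs, dtype=float)
    out["flagged"] = np.array(flags, dtype=bool)
    ok = out[~out["flagged"]]
    summary = (
        ok.groupby("pair_class")["correlation"]
        .agg(n_pairs="size", mean_r="mean", median_r="median")
        .reset_index()
    )
    summary["n_dropped_total"] = dropped
    return out, summary
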