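"""Module-level reporting: gene-to-eigengene correlations, module x biotype
counts, and GO-term overrepresentation by the hypergeometric test."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coexnet import GREY, Eigengene
from .models import ExpressionMatrix

TABLE_BIOTYPE_COLUMNS = ("antisense", "lincRNA", "other_lncRNA", "protein_coding", "pseudogene")


def _corr_pvalue(r: float, m: int) -> float:
    """Two-sided p from t = r sqrt((m-2)/(1-r^2)), m-2 df."""
    if m < 3:
        return 1.0
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((m - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=m - 2))


def eigengene_correlations(
    expr: ExpressionMatrix | pd.DataFrame,
    eigengenes: dict[str, Eigengene],
    assignment: pd.Series,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson and Spearman correlation of each gene to its module eigengene.

    Grey genes are skipped (noted in the ``skipped`` attribute of the
    returned frame's attrs).  p-values use the t approximation with m-2
    degrees of freedom for both coefficients.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    genes = list(assignment.index) if genes is None else list(genes)
    m = values.shape[1]
    rows, skipped = [], []
    for g in genes:
        module = assignment.get(g, GREY)
        if module == GREY or module not in eigengenes:
            skipped.append(g)
            continue
        x = values.loc[g].to_numpy(dtype=float)
        e = eigengenes[module].values.to_numpy()
        r = float(np.corrcoef(x, e)[0, 1])
        rho = float(np.corrcoef(stats.rankdata(x), stats.rankdata(e))[0, 1])
        rows.append((g, module, r, _corr_pvalue(r, m), rho, _corr_pvalue(rho, m)))
    out = pd.DataFrame(
        rows, columns=["gene_id", "module", "pear", "p.val_p", "spear", "p.val_s"]
    )
    out.attrs["skipped"] = skipped
    return out


def module_summary_table(assignment: pd.Series, biotypes: pd.Series) -> pd.DataFrame:
    """Counts of genes per module and biotype column.

    Small ncRNAs are folded into the other-lncRNA column so the table has
    the five canonical columns; row sums equal module sizes.  Grey is
    reported as its own row at the end.
    """
    bt = biotypes.reindex(assignment.index)
    bt = bt.replace({"small_ncRNA": "other_lncRNA"})
    table = pd.crosstab(assignment, bt)
    for col in TABLE_BIOTYPE_COLUMNS:
        if col not in table.columns:
            table[col] = 0
    table = table[list(TABLE_BIOTYPE_COLUMNS)]
    modules = [m for m in table.index if m != GREY]
    modules.sort(key=lambda m: -int(table.loc[m].sum()))
    order = modules + ([GREY] if GREY in table.index else [])
    table = table.loc[order]
    table.index.name = "module"
    return table


def hypergeometric_enrichment(
    module_genes: list[str],
    annotation: pd.DataFrame,
    universe: list[str] | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation of terms in a module.

    annotation: two-column frame (term_id, gene_id).  The universe defaults
    to all annotated genes.  Only terms with k >= 1 module gene are
    reported; q-values are Benjamini-Hochberg within the module.
    """
    if universe is None:
        universe = sorted(set(annotation["gene_id"]))
    universe_set = set(universe)
    module_set = set(module_genes) & universe_set
    ann = annotation[annotation["gene_id"].isin(universe_set)]
    n_universe = len(universe_set)
    n_module = len(module_set)
    rows = []
    for term, sub in ann.groupby("term_id", sort=True):
        term_genes = set(sub["gene_id"])
        K = len(term_genes)
        k = len(term_genes & module_set)
        if k < 1:
            continue
        p = float(stats.hypergeom.sf(k - 1, n_universe, K, n_module))
        rows.append((term, k, K, n_module, n_universe, p))
    out = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def module_enrichment(
    assignment: pd.Series, annotation: pd.DataFrame, p_threshold: float = 0.01
) -> pd.DataFrame:
    """Enrichment per non-grey module; top terms at raw p < threshold.

    Universe = network genes carrying at least one annotation.
    """
    network_genes = set(assignment.index)
    ann = annotation[annotation["gene_id"].isin(network_genes)]
    universe = sorted(set(ann["gene_id"]))
    frames = []
    for module in sorted(set(assignment) - {GREY}):
        genes = [g for g in assignment.index[assignment == module] if g in set(universe)]
        res = hypergeometric_enrichment(genes, ann, universe)
        res.insert(0, "module", module)
        frames.append(res[res["p"] < p_threshold])
    if not frames:
        return pd.DataFrame(columns=["module", "term_id", "k", "K", "n", "N", "p", "q"])
    return pd.concat(frames, ignore_index=True)
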