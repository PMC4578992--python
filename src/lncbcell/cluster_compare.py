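"""Sample clustering per gene class and dendrogram comparison.

Samples are clustered by average linkage on Pearson correlation distance
(d = 1 - r over a gene subset).  Two dendrograms over the same samples are
compared with Baker's Gamma: the Spearman correlation, over all unordered
leaf pairs, of the merge step at which each pair first shares a cluster.
Using merge steps rather than raw heights makes the coefficient invariant
to monotone height transformations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .models import ExpressionMatrix


@dataclass
class Dendrogram:
    """Average-linkage tree over samples: scipy linkage matrix + leaf ids."""

    linkage: np.ndarray
    leaves: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def merge_step_matrix(self) -> np.ndarray:
        """merge_steps[i, j] = 1-based merge step at which leaves i and j
        first share a cluster; 0 on the diagonal."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        steps = np.zeros((n, n), dtype=int)
        for k, (a, b, _h, _c) in enumerate(self.linkage, start=1):
            ma, mb = members.pop(int(a)), members.pop(int(b))
            for i in ma:
                for j in mb:
                    steps[i, j] = steps[j, i] = k
            members[n + k - 1] = ma + mb
        return steps

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        root = to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.leaves[node.id]
            parts = ",".join(
                f"{rec(ch)}:{(node.dist - ch.dist):.6g}"
                for ch in (node.left, node.right)
            )
            return f"({parts})"

        return rec(root) + ";"


def correlation_distance(expr: ExpressionMatrix, gene_subset) -> pd.DataFrame:
    """Sample x sample dissimilarity d(s, t) = 1 - Pearson r over the genes."""
    genes = list(gene_subset)
    if not genes:
        raise ValueError("gene subset is empty")
    sub = expr.values.loc[genes]
    if sub.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = sub.std(axis=0, ddof=0)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance sample vector(s): {flat}")
    d = 1.0 - np.corrcoef(sub.to_numpy(), rowvar=False)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=sub.columns, columns=sub.columns)


def hierarchical_cluster(dissimilarity: pd.DataFrame) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a square dissimilarity."""
    d = dissimilarity.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity must be square and symmetric")
    z = average(squareform(d, checks=False))
    return Dendrogram(z, list(dissimilarity.columns))


def bakers_gamma(tree1: Dendrogram, tree2: Dendrogram) -> float:
    """Rank correlation of pairwise first-merge steps between two trees."""
    if set(tree1.leaves) != set(tree2.leaves):
        raise ValueError("trees have different leaf sets")
    order = {leaf: i for i, leaf in enumerate(tree1.leaves)}
    perm = np.array([order[leaf] for leaf in tree2.leaves])
    m1 = tree1.merge_step_matrix()
    m2_raw = tree2.merge_step_matrix()
    n = tree1.n_leaves
    m2 = np.zeros_like(m2_raw)
    m2[np.ix_(perm, perm)] = m2_raw
    iu = np.triu_indices(n, k=1)
    rho, _ = spearmanr(m1[iu], m2[iu])
    return float(rho)


def class_dendrograms(
    expr: ExpressionMatrix, gene_classes: dict[str, list[str]]
) -> dict[str, Dendrogram]:
    """One sample dendrogram per gene class (e.g. protein-coding, lncRNA)."""
    return {
        name: hierarchical_cluster(correlation_distance(expr, genes))
        for name, genes in gene_classes.items()
        if genes
    }


def gamma_table(dendros: dict[str, Dendrogram]) -> pd.DataFrame:
    """Pairwise Baker's Gamma between class-specific sample dendrograms."""
    names = list(dendros)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            rows.append((a, b, bakers_gamma(dendros[a], dendros[b])))
    return pd.DataFrame(rows, columns=["class_a", "class_b", "bakers_gamma"])
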