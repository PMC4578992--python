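"""Weighted gene co-expression network: soft-threshold adjacency,
topological overlap, module detection, eigengenes, merging, connectivity.

The network is unsigned by default (a_ij = |cor|^beta, beta = 6); modules
are branches of an average-linkage tree on 1 - TOM obtained by a static
height cut, labelled by the conventional size-ranked color sequence
(turquoise, blue, brown, ...), with genes in no module labelled grey.
Each module is summarized by its eigengene — the first principal component
of the standardized member expression — oriented to correlate positively
with the mean member profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .models import ExpressionMatrix

logger = logging.getLogger(__name__)

MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)
GREY = "grey"


@dataclass
class NetworkConfig:
    network_type: str = "unsigned"
    beta: int = 6
    candidate_betas: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16, 18, 20)
    scale_free_r2_target: float = 0.8
    # static cut as a fraction of the maximum merge height; placed below the
    # top merges where unassigned genes attach to the tree (recovery of
    # planted modules is flat over ~0.90-0.96, see docs/methods.md)
    cut_height: float = 0.95
    min_module_size: int = 30
    merge_height: float = 0.25     # eigengene dissimilarity below which modules merge

    def __post_init__(self) -> None:
        if self.network_type not in ("unsigned", "signed"):
            raise ValueError("network_type must be 'unsigned' or 'signed'")
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.cut_height <= 1:
            raise ValueError("cut_height must be in (0, 1]")


@dataclass
class Eigengene:
    values: pd.Series            # per-sample, unit norm
    variance_explained: float


def adjacency(
    expr: ExpressionMatrix | pd.DataFrame, config: NetworkConfig | None = None
) -> pd.DataFrame:
    """Soft-threshold co-expression adjacency.

    unsigned: |cor|^beta; signed: ((1 + cor) / 2)^beta; unit diagonal.
    """
    config = config or NetworkConfig()
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    x = values.to_numpy(dtype=float)
    if x.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = values.index[sd == 0].tolist()
        raise ValueError(f"zero-variance genes in network input: {bad[:5]}")
    r = np.corrcoef(x)
    if config.network_type == "unsigned":
        a = np.abs(r) ** config.beta
    else:
        a = ((1.0 + r) / 2.0) ** config.beta
    np.fill_diagonal(a, 1.0)
    a = np.clip((a + a.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(a, index=values.index, columns=values.index)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 and slope of log10 p(k) vs log10 k over connectivity bins."""
    k = np.asarray(k, dtype=float)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k, p_k = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mean_k.append(k[mask].mean())
        p_k.append(mask.mean())
    mean_k, p_k = np.asarray(mean_k), np.asarray(p_k)
    ok = (mean_k > 0) & (p_k > 0)
    if ok.sum() < 3:
        return 0.0, 0.0
    lx, ly = np.log10(mean_k[ok]), np.log10(p_k[ok])
    slope, _intercept = np.polyfit(lx, ly, 1)
    r = np.corrcoef(lx, ly)[0, 1]
    r2 = float(r * r)
    if slope > 0:
        r2 = -r2
    return r2, float(slope)


def pick_soft_threshold(
    expr: ExpressionMatrix | pd.DataFrame, config: NetworkConfig | None = None
) -> tuple[int, pd.DataFrame]:
    """Choose the smallest beta reaching the scale-free topology target R^2.

    Falls back to the argmax-R^2 beta (with a warning) when no candidate
    reaches the target, and to the default beta for very small inputs.
    """
    config = config or NetworkConfig()
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if values.shape[0] < 30:
        warnings.warn("fewer than 30 genes; falling back to default beta")
        return config.beta, pd.DataFrame(
            columns=["beta", "r2", "slope", "mean_k"]
        )
    rows = []
    chosen = None
    for beta in sorted(config.candidate_betas):
        cfg = NetworkConfig(
            network_type=config.network_type, beta=beta,
            cut_height=config.cut_height,
        )
        a = adjacency(values, cfg).to_numpy()
        k = a.sum(axis=1) - 1.0
        r2, slope = scale_free_fit(k)
        rows.append((beta, r2, slope, float(k.mean())))
        if chosen is None and r2 >= config.scale_free_r2_target:
            chosen = beta
    table = pd.DataFrame(rows, columns=["beta", "r2", "slope", "mean_k"])
    if chosen is None:
        chosen = int(table.loc[table["r2"].idxmax(), "beta"])
        logger.warning(
            "no beta reached scale-free R^2 target %.2f; using argmax beta %d",
            config.scale_free_r2_target, chosen,
        )
    return int(chosen), table


def tom(a: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a symmetric unit-diagonal adjacency."""
    A = a.to_numpy(dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    n = A.shape[0]
    L = A @ A
    # shared-neighbor sums excluding i and j themselves (diagonal is 1)
    l_ij = L - A - A.T  # removes a_ii*a_ij and a_ij*a_jj terms
    k = A.sum(axis=1) - 1.0
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = (l_ij + A) / (kmin + 1.0 - A)
    omega = np.nan_to_num(omega, nan=0.0, posinf=0.0)
    np.fill_diagonal(omega, 1.0)
    omega = np.clip((omega + omega.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(omega, index=a.index, columns=a.columns)


def detect_modules(
    omega: pd.DataFrame, config: NetworkConfig | None = None
) -> tuple[pd.Series, np.ndarray]:
    """Static-cut module detection on the 1 - TOM gene tree.

    Returns (gene -> color label Series, linkage matrix).  Clusters smaller
    than min_module_size become grey; surviving clusters are labelled by
    the color sequence in decreasing size order.
    """
    config = config or NetworkConfig()
    d = 1.0 - omega.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    z = average(squareform(d, checks=False))
    max_h = z[:, 2].max() if len(z) else 0.0
    clusters = fcluster(z, t=config.cut_height * max_h, criterion="distance")
    labels = pd.Series(GREY, index=omega.index, dtype=object)
    sizes = pd.Series(clusters).value_counts()
    big = [c for c in sizes.index if sizes[c] >= config.min_module_size]
    # stable ordering: by size desc, then by cluster id
    big.sort(key=lambda c: (-sizes[c], c))
    if not big:
        warnings.warn("static cut produced no module of minimum size; all grey")
    for rank, c in enumerate(big):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        labels.iloc[np.nonzero(clusters == c)[0]] = color
    return labels, z


def module_eigengene(
    expr: ExpressionMatrix | pd.DataFrame, assignment: pd.Series
) -> dict[str, Eigengene]:
    """First principal component summary per module (grey excluded).

    Member genes are standardized across samples; the eigengene is the
    first right singular vector, sign-oriented so its correlation with the
    mean standardized member profile is >= 0.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    out: dict[str, Eigengene] = {}
    for module in sorted(set(assignment) - {GREY}):
        genes = assignment.index[assignment == module]
        if len(genes) < 2:
            raise ValueError(f"module {module} has fewer than 2 genes")
        x = values.loc[genes].to_numpy(dtype=float)
        x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        v = vt[0]
        mean_profile = x.mean(axis=0)
        if np.dot(v, mean_profile) < 0:
            v = -v
        out[module] = Eigengene(
            values=pd.Series(v, index=values.columns, name=module),
            variance_explained=float(s[0] ** 2 / (s**2).sum()),
        )
    return out


def merge_modules(
    expr: ExpressionMatrix | pd.DataFrame,
    assignment: pd.Series,
    merge_height: float = 0.25,
) -> tuple[pd.Series, dict[str, Eigengene]]:
    """Merge modules whose eigengenes cluster below ``merge_height``
    (dissimilarity 1 - cor, average linkage); one merge pass, then
    eigengenes are recomputed."""
    eigs = module_eigengene(expr, assignment)
    modules = sorted(eigs)
    if merge_height > 0 and len(modules) >= 2:
        e = np.vstack([eigs[m].values.to_numpy() for m in modules])
        d = 1.0 - np.corrcoef(e)
        np.fill_diagonal(d, 0.0)
        z = average(squareform(d, checks=False))
        groups = fcluster(z, t=merge_height, criterion="distance")
        sizes = assignment.value_counts()
        new_assignment = assignment.copy()
        for gid in np.unique(groups):
            members = [m for m, g in zip(modules, groups) if g == gid]
            if len(members) > 1:
                keep = max(members, key=lambda m: (sizes.get(m, 0), m))
                for m in members:
                    if m != keep:
                        new_assignment[new_assignment == m] = keep
        assignment = new_assignment
        eigs = module_eigengene(expr, assignment)
    return assignment, eigs


def intramodular_connectivity(a: pd.DataFrame, assignment: pd.Series) -> pd.Series:
    """kWithin(i) = sum of adjacencies to same-module genes (grey included,
    computed within grey, but grey is not a module)."""
    A = a.to_numpy(dtype=float)
    k = pd.Series(0.0, index=a.index)
    for module in set(assignment):
        idx = np.nonzero((assignment == module).to_numpy())[0]
        block = A[np.ix_(idx, idx)]
        k.iloc[idx] = block.sum(axis=1) - 1.0  # exclude self (a_ii = 1)
    return k


def top_hubs(
    kwithin: pd.Series, assignment: pd.Series, module: str, n: int = 10
) -> list[str]:
    """The n genes of a module with the largest intramodular connectivity;
    ties broken by gene id."""
    genes = assignment.index[assignment == module]
    ranked = sorted(genes, key=lambda g: (-kwithin[g], g))
    return ranked[:n]


def export_edges(
    a: pd.DataFrame,
    assignment: pd.Series,
    biotypes: pd.Series | None = None,
    threshold: float | None = None,
    top_fraction: float | None = None,
) -> pd.DataFrame:
    """Unordered edge table for network visualization.

    Selection is either adjacency >= threshold or the top fraction of all
    edges; exactly one of the two must be given.
    """
    if (threshold is None) == (top_fraction is None):
        raise ValueError("give exactly one of threshold / top_fraction")
    A = a.to_numpy(dtype=float)
    genes = list(a.index)
    iu = np.triu_indices(len(genes), k=1)
    w = A[iu]
    if threshold is not None:
        keep = w >= threshold
    else:
        m = int(round(top_fraction * len(w)))
        keep = np.zeros(len(w), dtype=bool)
        if m > 0:
            keep[np.argsort(-w, kind="stable")[:m]] = True
    if not keep.any():
        warnings.warn("edge selection is empty")
    rows = []
    for i, j, adj in zip(iu[0][keep], iu[1][keep], w[keep]):
        ga, gb = genes[i], genes[j]
        rows.append(
            (
                ga, gb, float(adj),
                assignment.get(ga, GREY), assignment.get(gb, GREY),
                biotypes.get(ga, "") if biotypes is not None else "",
                biotypes.get(gb, "") if biotypes is not None else "",
            )
        )
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "adjacency", "module_a", "module_b", "biotype_a", "biotype_b"],
    )
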