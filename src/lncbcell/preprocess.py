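"""RMA-style preprocessing: quantile normalization and median-polish
summarization of gene-level probe sets to log2 expression.

The background-correction convolution of classic RMA is intentionally not
applied; detection against antigenomic background probe sets (see
``lncbcell.filters``) is the operative background treatment downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .models import ExpressionMatrix, ProbeSetMap


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean empirical distribution.

    The reference distribution is the across-column mean of each order
    statistic; ties within a column receive the mean of the reference
    values at their (average) rank positions, so rank order is preserved.
    """
    if matrix.isna().any().any():
        raise ValueError("quantile_normalize: input contains NaN")
    if matrix.shape[1] < 2:
        raise ValueError("quantile_normalize: need at least 2 columns")
    x = matrix.to_numpy(dtype=float)
    n = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def median_polish_summarize(
    probe_values: np.ndarray, tol: float = 1e-6, max_iter: int = 50
) -> np.ndarray:
    """Per-sample summary of a probes x samples block by median polish.

    Fits value ~ overall + probe effect + sample effect with alternating
    row/column median sweeps; returns overall + sample effects (one value
    per sample).
    """
    z = np.asarray(probe_values, dtype=float)
    if z.ndim != 2 or z.size == 0:
        raise ValueError("median_polish_summarize: need a non-empty 2-D array")
    z = z.copy()
    overall = 0.0
    row_eff = np.zeros(z.shape[0])
    col_eff = np.zeros(z.shape[1])
    for _ in range(max_iter):
        rdelta = np.median(z, axis=1)
        z -= rdelta[:, None]
        row_eff += rdelta
        delta = np.median(col_eff)
        col_eff -= delta
        overall += delta
        cdelta = np.median(z, axis=0)
        z -= cdelta[None, :]
        col_eff += cdelta
        delta = np.median(row_eff)
        row_eff -= delta
        overall += delta
        change = max(np.max(np.abs(rdelta)), np.max(np.abs(cdelta)))
        if change < tol:
            break
    return overall + col_eff


def rma(
    probe_matrix: pd.DataFrame,
    probe_map: ProbeSetMap,
    metadata: pd.DataFrame,
) -> ExpressionMatrix:
    """log2 -> joint quantile normalization over assigned probes -> per-gene
    median polish.  ``probe_matrix`` holds raw linear intensities (> 0).

    Output rows are ordered by gene_id.
    """
    assigned = [p for ps in probe_map.gene_to_probes.values() for p in ps]
    missing = sorted(set(assigned) - set(probe_matrix.index))
    if missing:
        raise ValueError(
            f"{len(missing)} mapped probes absent from intensity matrix: {missing[:5]}"
        )
    sub = probe_matrix.loc[assigned]
    if (sub.to_numpy() <= 0).any():
        raise ValueError("rma expects positive linear intensities")
    logged = np.log2(sub)
    if logged.shape[1] >= 2:
        normalized = quantile_normalize(logged)
    else:
        normalized = logged
    values = {}
    for gene_id in sorted(probe_map.gene_to_probes):
        block = normalized.loc[probe_map.gene_to_probes[gene_id]].to_numpy()
        values[gene_id] = median_polish_summarize(block)
    expr = pd.DataFrame.from_dict(values, orient="index", columns=probe_matrix.columns)
    return ExpressionMatrix(expr, metadata)
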