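"""Detection and variance filtering ahead of network analysis.

Detection works against *constructed* background probe sets: antigenomic
probes are repeatedly resampled to match real probe sets in probe count
and GC-content distribution, summarized exactly like real probe sets, and
pooled; the detection threshold is two standard deviations above the mean
of the pooled summaries.  A gene is detected if it exceeds the threshold
in every sample of at least one B-cell subset.  Separately, genes with
expression standard deviation < 0.5 across all samples are dropped as
uninformative for co-expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ExpressionMatrix, ProbeSetMap
from .preprocess import median_polish_summarize


@dataclass
class BackgroundModel:
    """Pooled summaries of constructed background probe sets."""

    summaries: np.ndarray  # pooled per-sample values over all draws
    n_draws: int
    seed: int
    gc_bin_width: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.summaries))

    @property
    def sd(self) -> float:
        return float(np.std(self.summaries, ddof=1))

    @property
    def threshold(self) -> float:
        return compute_intensity_threshold(self)

    def report(self) -> dict:
        return {
            "mu_bg": self.mean,
            "sigma_bg": self.sd,
            "tau": self.threshold,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "gc_bin_width": self.gc_bin_width,
        }


def _gc_bin(gc: np.ndarray, width: float) -> np.ndarray:
    return np.floor(np.asarray(gc, dtype=float) / width).astype(int)


def sample_background_sets(
    background_probes: pd.DataFrame,
    background_values: pd.DataFrame,
    probe_map: ProbeSetMap,
    probe_gc: pd.Series,
    n_draws: int = 1000,
    seed: int = 0,
    gc_bin_width: float = 0.05,
) -> BackgroundModel:
    """Construct background probe sets matched to real sets and summarize.

    For each draw a real probe set is chosen round-robin; background probes
    are sampled without replacement to match its probe count, stratified by
    GC bins so the drawn GC histogram matches the real set's (falling back
    to the nearest non-exhausted bin).  Each constructed set is summarized
    with median polish on log2 values; all per-sample summaries are pooled.

    Parameters
    ----------
    background_probes : table with probe_id and gc_fraction for antigenomic probes
    background_values : log2 intensities of those probes (probes x samples)
    probe_map : filtered gene-level probe sets (the "real" sets)
    probe_gc : gc_fraction per real probe id
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not probe_map.gene_to_probes:
        raise ValueError("no real probe sets to match")
    rng = np.random.default_rng(seed)
    bg_gc = background_probes.set_index("probe_id")["gc_fraction"]
    bg_ids = bg_gc.index.to_numpy()
    bg_bins = _gc_bin(bg_gc.to_numpy(), gc_bin_width)
    by_bin: dict[int, np.ndarray] = {
        b: bg_ids[bg_bins == b] for b in np.unique(bg_bins)
    }
    available_bins = np.array(sorted(by_bin))

    real_sets = sorted(probe_map.gene_to_probes)
    pooled = []
    for draw in range(n_draws):
        gene = real_sets[draw % len(real_sets)]
        probes = probe_map.gene_to_probes[gene]
        want_bins = _gc_bin(probe_gc.loc[probes].to_numpy(), gc_bin_width)
        taken: dict[int, int] = {}
        chosen: list[str] = []
        for b in want_bins:
            # nearest bin with probes left
            order = available_bins[np.argsort(np.abs(available_bins - b), kind="stable")]
            for cand in order:
                used = taken.get(cand, 0)
                pool = by_bin[int(cand)]
                if used < len(pool):
                    pick = rng.choice(np.setdiff1d(pool, chosen, assume_unique=False))
                    chosen.append(str(pick))
                    taken[cand] = used + 1
                    break
            else:
                raise ValueError(
                    "background probes exhausted; widen gc_bin_width or add probes"
                )
        block = background_values.loc[chosen].to_numpy()
        pooled.append(median_polish_summarize(block))
    return BackgroundModel(
        summaries=np.concatenate(pooled),
        n_draws=n_draws,
        seed=seed,
        gc_bin_width=gc_bin_width,
    )


def compute_intensity_threshold(model: BackgroundModel) -> float:
    """tau = mean + 2 * sample SD (ddof=1) of pooled constructed-set values."""
    vals = np.asarray(model.summaries, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 pooled background values")
    return float(vals.mean() + 2.0 * vals.std(ddof=1))


def detection_filter(expr: ExpressionMatrix, tau: float) -> list[str]:
    """Genes expressed above ``tau`` in *all* samples of >= 1 subset.

    The inequality is strict; subsets with zero samples are ignored.
    """
    meta = expr.metadata.set_index("sample_id")["subset"]
    retained = []
    values = expr.values
    groups = [
        values.loc[:, meta.index[meta == s].intersection(values.columns)]
        for s in meta.unique()
    ]
    groups = [g for g in groups if g.shape[1] > 0]
    above = np.column_stack([(g.to_numpy() > tau).all(axis=1) for g in groups])
    keep = above.any(axis=1)
    retained = values.index[keep].tolist()
    return retained


def variance_filter(expr: ExpressionMatrix, min_sd: float = 0.5) -> list[str]:
    """Genes with sample SD (ddof=1) across all samples >= ``min_sd``."""
    if expr.values.shape[1] < 2:
        raise ValueError("variance filter needs >= 2 samples")
    sd = expr.values.std(axis=1, ddof=1)
    return expr.values.index[sd >= min_sd].tolist()


def network_input_genes(
    expr: ExpressionMatrix, tau: float, min_sd: float = 0.5
) -> pd.DataFrame:
    """Apply both filters; returns a per-gene table with a reason column.

    Reasons: ``retained``, ``not_detected``, ``low_variance`` (a gene
    failing both is reported as not_detected).
    """
    detected = set(detection_filter(expr, tau))
    variable = set(variance_filter(expr, min_sd))
    reason = []
    for g in expr.values.index:
        if g not in detected:
            reason.append("not_detected")
        elif g not in variable:
            reason.append("low_variance")
        else:
            reason.append("retained")
    return pd.DataFrame({"gene_id": expr.values.index, "reason": reason})
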