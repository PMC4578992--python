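"""End-to-end orchestration: simulate -> remap -> RMA -> filters ->
annotation -> sample-cluster comparison -> co-expression network ->
module reporting, plus the independent FACS gating stage.

All randomness flows from one global seed; each stage draws from its own
derived substream so toggling a stage does not shift another's stream.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, cluster_compare, coexnet, downstream, facs_gate, filters
from .io import write_matrix_tsv, write_tsv
from .models import LNCRNA_CLASSES, ExpressionMatrix
from .preprocess import rma
from .remap import assign_probes, filter_probe_sets
from .synthetic_data import SimulationConfig, simulate_study, write_study

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str | Path = "lncbcell_run"
    simulation: SimulationConfig | None = None   # built from seed when None
    min_probes: int = 4
    n_background_draws: int = 1000
    gc_bin_width: float = 0.05
    min_sd: float = 0.5
    max_gap: int = 1000
    network: coexnet.NetworkConfig = field(default_factory=coexnet.NetworkConfig)
    pick_beta: bool = False          # default: fixed beta from `network`
    facs_max_depth: int = 3
    run_filters: bool = True
    write_outputs: bool = True
    edge_top_fraction: float = 0.05


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage on a simulated study; returns the run report.

    The report carries per-stage counts and parameters; intermediate tables
    are written under ``config.outdir`` when ``write_outputs`` is set.
    """
    t_start = time.time()
    outdir = Path(config.outdir)
    if config.write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    def stage_done(name: str, t0: float, **counts) -> None:
        report["stages"][name] = {"seconds": round(time.time() - t0, 2), **counts}
        logger.info("stage %s done in %.1fs %s", name, time.time() - t0, counts)

    # --- simulate -------------------------------------------------------
    t0 = time.time()
    sim_config = config.simulation or SimulationConfig(seed=stage_seed(config.seed, "simulate"))
    study = simulate_study(sim_config)
    if config.write_outputs:
        write_study(study, outdir / "inputs")
    truth = study["ground_truth"]
    gene_models = study["gene_models"]
    stage_done(
        "simulate", t0,
        n_genes=len(gene_models.genes), n_probes=len(study["probes"]),
        n_samples=len(study["metadata"]),
    )

    # --- remap ----------------------------------------------------------
    t0 = time.time()
    probe_map = assign_probes(study["probes"], gene_models)
    probe_map, remap_report = filter_probe_sets(probe_map, config.min_probes)
    status_counts = probe_map.counts()
    stage_done(
        "remap", t0,
        **status_counts, genes_retained=remap_report.retained_genes,
        genes_removed_small_sets=len(remap_report.removed_genes),
    )

    # --- rma ------------------------------------------------------------
    t0 = time.time()
    expr = rma(study["intensities"], probe_map, study["metadata"])
    if config.write_outputs:
        write_matrix_tsv(expr.values, outdir / "expression.tsv")
    stage_done("rma", t0, n_genes=expr.values.shape[0], n_samples=expr.values.shape[1])

    # --- filters --------------------------------------------------------
    t0 = time.time()
    bg_probes = study["probes"][study["probes"]["is_background"]]
    bg_values = np.log2(study["intensities"].loc[bg_probes["probe_id"]])
    probe_gc = study["probes"].set_index("probe_id")["gc_fraction"]
    bg_model = filters.sample_background_sets(
        bg_probes, bg_values, probe_map, probe_gc,
        n_draws=config.n_background_draws,
        seed=stage_seed(config.seed, "filters"),
        gc_bin_width=config.gc_bin_width,
    )
    tau = bg_model.threshold
    if config.run_filters:
        gene_table = filters.network_input_genes(expr, tau, config.min_sd)
        network_genes = gene_table.loc[gene_table["reason"] == "retained", "gene_id"].tolist()
    else:
        gene_table = pd.DataFrame(
            {"gene_id": expr.values.index, "reason": "retained"}
        )
        network_genes = expr.values.index.tolist()
    if config.write_outputs:
        write_tsv(gene_table, outdir / "gene_filters.tsv")
        with open(outdir / "background_model.json", "w") as fh:
            json.dump(bg_model.report(), fh, indent=2)
    net_expr = expr.select_genes(network_genes)
    stage_done(
        "filters", t0, tau=round(tau, 4),
        n_detected=int((gene_table["reason"] != "not_detected").sum()),
        n_network_genes=len(network_genes),
    )

    # --- annotate -------------------------------------------------------
    t0 = time.time()
    coding_summary = annotate.summarize_coding_potential(study["coding"])
    pairs = annotate.find_local_pairs(gene_models, config.max_gap)
    pairs_corr, pair_summary = annotate.pair_coexpression(pairs, expr)
    if config.write_outputs:
        write_tsv(coding_summary, outdir / "coding_summary.tsv")
        write_tsv(pairs_corr, outdir / "local_pairs.tsv")
        write_tsv(pair_summary, outdir / "local_pair_summary.tsv")
    stage_done("annotate", t0, n_local_pairs=len(pairs), n_pairs_with_expression=len(pairs_corr))

    # --- cluster comparison ---------------------------------------------
    t0 = time.time()
    biotypes = gene_models.biotype_map()
    net_bt = biotypes.reindex(net_expr.values.index)
    gene_classes = {
        "protein_coding": net_expr.values.index[net_bt == "protein_coding"].tolist(),
        "lncRNA": net_expr.values.index[net_bt.isin(LNCRNA_CLASSES)].tolist(),
        "lincRNA": net_expr.values.index[net_bt == "lincRNA"].tolist(),
        "antisense": net_expr.values.index[net_bt == "antisense"].tolist(),
    }
    dendros = cluster_compare.class_dendrograms(net_expr, gene_classes)
    gammas = cluster_compare.gamma_table(dendros)
    if config.write_outputs:
        write_tsv(gammas, outdir / "bakers_gamma.tsv")
        for name, dend in dendros.items():
            (outdir / f"samples_{name}.nwk").write_text(dend.to_newick() + "\n")
    stage_done("cluster_compare", t0, n_class_trees=len(dendros))

    # --- network --------------------------------------------------------
    t0 = time.time()
    net_cfg = config.network
    if config.pick_beta:
        beta, fit_table = coexnet.pick_soft_threshold(net_expr, net_cfg)
        net_cfg = coexnet.NetworkConfig(
            network_type=net_cfg.network_type, beta=beta,
            cut_height=net_cfg.cut_height, min_module_size=net_cfg.min_module_size,
            merge_height=net_cfg.merge_height,
        )
    else:
        fit_table = None
    adj = coexnet.adjacency(net_expr, net_cfg)
    omega = coexnet.tom(adj)
    assignment, _gene_tree = coexnet.detect_modules(omega, net_cfg)
    assignment, eigengenes = coexnet.merge_modules(
        net_expr, assignment, net_cfg.merge_height
    )
    kwithin = coexnet.intramodular_connectivity(adj, assignment)
    edges = coexnet.export_edges(
        adj, assignment, biotypes, top_fraction=config.edge_top_fraction
    )
    module_sizes = assignment.value_counts().to_dict()
    if config.write_outputs:
        write_tsv(
            pd.DataFrame({"gene_id": assignment.index, "module": assignment.to_numpy(),
                          "kWithin": kwithin.reindex(assignment.index).to_numpy()}),
            outdir / "modules.tsv",
        )
        eig_df = pd.DataFrame({m: e.values for m, e in eigengenes.items()}).T
        write_matrix_tsv(eig_df, outdir / "eigengenes.tsv")
        write_tsv(edges, outdir / "edges.tsv")
        if fit_table is not None:
            write_tsv(fit_table, outdir / "soft_threshold_fit.tsv")
    stage_done(
        "network", t0, beta=net_cfg.beta,
        n_modules=len(eigengenes), module_sizes=module_sizes,
    )

    # --- downstream -----------------------------------------------------
    t0 = time.time()
    summary = downstream.module_summary_table(assignment, biotypes)
    lnc_genes = [g for g in assignment.index if biotypes.get(g) in LNCRNA_CLASSES]
    eig_corr = downstream.eigengene_correlations(net_expr, eigengenes, assignment, lnc_genes)
    enrichment = downstream.module_enrichment(assignment, study["go"])
    if config.write_outputs:
        write_tsv(summary.reset_index(), outdir / "module_biotype_table.tsv")
        write_tsv(eig_corr, outdir / "lncRNA_eigengene_correlations.tsv")
        write_tsv(enrichment, outdir / "go_enrichment.tsv")
    stage_done(
        "downstream", t0,
        n_lncRNA_rows=len(eig_corr), n_enriched_terms=len(enrichment),
    )

    # --- FACS gating ------------------------------------------------------
    t0 = time.time()
    facs_results = {}
    for tissue, (events, labels) in study["facs"].items():
        markers = [c for c in events.columns if c != "tissue"]
        tree = facs_gate.build_tree(
            events[markers], labels, max_depth=config.facs_max_depth
        )
        routed = facs_gate.apply_tree(tree, events[markers])
        acc = float((routed["label"].to_numpy() == labels.to_numpy()).mean())
        facs_results[tissue] = {"resubstitution_accuracy": acc, "depth": tree.depth()}
        if config.write_outputs:
            tree.to_json(outdir / f"gate_tree_{tissue}.json")
    stage_done("facs_gate", t0, **{
        f"{t}_accuracy": round(v["resubstitution_accuracy"], 4)
        for t, v in facs_results.items()
    })

    report["elapsed_seconds"] = round(time.time() - t_start, 2)
    report["results"] = {
        "tau": tau,
        "module_sizes": module_sizes,
        "facs": facs_results,
        "bakers_gamma": gammas.to_dict(orient="records"),
        "pair_summary": pair_summary.to_dict(orient="records"),
    }
    # objects for programmatic use (not serialized)
    report["objects"] = {
        "study": study,
        "truth": truth,
        "expr": expr,
        "net_expr": net_expr,
        "probe_map": probe_map,
        "assignment": assignment,
        "eigengenes": eigengenes,
        "adjacency": adj,
        "dendrograms": dendros,
        "gammas": gammas,
        "pairs": pairs_corr,
        "pair_summary": pair_summary,
        "gene_table": gene_table,
        "enrichment": enrichment,
        "module_table": summary,
        "facs_results": facs_results,
        "bg_model": bg_model,
    }
    if config.write_outputs:
        serializable = {k: v for k, v in report.items() if k != "objects"}
        with open(outdir / "run_report.json", "w") as fh:
            json.dump(serializable, fh, indent=2, default=str)
    return report
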