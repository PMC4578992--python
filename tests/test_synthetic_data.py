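"""Generator tests: determinism, conservation, planted-structure calibration."""

import io

import numpy as np
import pandas as pd
import pytest

from lncbcell.io import write_gtf
from lncbcell.models import ALL_SUBSETS, BIOTYPES
from lncbcell.synthetic_data import (
    SimulationConfig,
    default_module_profiles,
    generate_gene_models,
    generate_probes,
    simulate_expression,
    simulate_facs,
)

from conftest import small_sim_config


def _gtf_bytes(gene_models) -> str:
    buf = io.StringIO()
    # write_gtf expects a path; use a temp-less round trip via file object shim
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as d:
        p = pathlib.Path(d) / "x.gtf"
        write_gtf(gene_models, p)
        return p.read_text()


class TestConfigValidation:
    def test_unknown_subset_in_design_rejected(self):
        with pytest.raises(ValueError, match="unknown subset"):
            SimulationConfig(sample_design=[("bone_marrow", "blast", "D1")])

    def test_within_module_cor_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(within_module_cor=1.0)

    def test_module_sizes_must_match_modules(self):
        with pytest.raises(ValueError, match="one size per module"):
            SimulationConfig(genes_per_module=(10, 10))

    def test_profiles_orthogonal_and_standardized(self):
        prof = pd.DataFrame(default_module_profiles(7)).T[list(ALL_SUBSETS)]
        v = prof.to_numpy()
        gram = v @ v.T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-9
        assert np.allclose(v.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(v.std(axis=1), 1, atol=1e-12)


class TestGeneModels:
    def test_zero_genes_of_a_biotype(self):
        cfg = small_sim_config()
        counts = dict(cfg.n_genes_per_biotype)
        counts["other_lncRNA"] = 0
        cfg2 = small_sim_config()
        cfg2.n_genes_per_biotype = counts
        gm, _ = generate_gene_models(cfg2)
        assert (gm.genes["biotype"] == "other_lncRNA").sum() == 0

    def test_deterministic_gtf_output(self, small_config):
        gm1, _ = generate_gene_models(small_config)
        gm2, _ = generate_gene_models(small_sim_config())
        assert _gtf_bytes(gm1) == _gtf_bytes(gm2)

    def test_antisense_pair_geometry(self, small_study):
        gm = small_study["gene_models"]
        truth = small_study["ground_truth"]
        spans = gm.genes.set_index("gene_id")
        anti = truth.pairs[truth.pairs["pair_class"] == "antisense_mRNA"]
        assert set(anti["overlap_class"]) == {
            "head_to_head", "tail_to_tail", "fully_overlapping"
        }
        for row in anti.itertuples(index=False):
            a, b = spans.loc[row.gene_a], spans.loc[row.gene_b]
            assert a.strand != b.strand
            assert max(a.start, b.start) < min(a.end, b.end)  # overlap
            if row.overlap_class == "fully_overlapping":
                assert a.start <= b.start and b.end <= a.end
            elif row.overlap_class == "tail_to_tail":
                plus, minus = (a, b) if a.strand == "+" else (b, a)
                assert minus.start < plus.end <= minus.end  # 3' ends overlap
            else:  # head_to_head: 5' ends inside the overlap
                plus, minus = (a, b) if a.strand == "+" else (b, a)
                assert minus.start <= plus.start < minus.end

    def test_neighbor_pairs_within_1kb_and_controls_beyond(self, small_study):
        gm = small_study["gene_models"]
        truth = small_study["ground_truth"]
        spans = gm.genes.set_index("gene_id")

        def gap(ga, gb):
            a, b = spans.loc[ga], spans.loc[gb]
            return max(0, max(a.start, b.start) - min(a.end, b.end))

        for row in truth.pairs.itertuples(index=False):
            if row.pair_class in ("lincRNA_mRNA", "mRNA_mRNA"):
                assert gap(row.gene_a, row.gene_b) <= 1000
            if row.pair_class == "control":
                assert gap(row.gene_a, row.gene_b) > 1000

    def test_ground_truth_conservation(self, small_study):
        gm = small_study["gene_models"]
        truth = small_study["ground_truth"]
        all_genes = set(gm.gene_ids)
        assert set(truth.gene_module) == all_genes
        assert set(truth.filter_fail["gene_id"]) <= all_genes
        module_genes = set(truth.module_genes())
        assert module_genes.isdisjoint(set(truth.filter_fail["gene_id"]))
        assert set(small_study["intensities"].index) == set(
            small_study["probes"]["probe_id"]
        )

    def test_chromosome_too_short_raises(self):
        cfg = small_sim_config()
        cfg.chrom_length = 50_000
        with pytest.raises(ValueError, match="too short"):
            generate_gene_models(cfg)


class TestProbes:
    @pytest.mark.parametrize("stale,expect_contained", [(0.0, True), (1.0, False)])
    def test_stale_fraction_extremes(self, stale, expect_contained):
        cfg = small_sim_config()
        cfg.stale_probe_fraction = stale
        gm, _ = generate_gene_models(cfg)
        probes = generate_probes(gm, cfg)
        gene_probes = probes[~probes["is_background"]]
        ex = gm.exons_by_gene()
        exons_by_gene = {
            g: list(zip(sub["start"], sub["end"]))
            for g, sub in ex.groupby("gene_id", sort=False)
        }
        contained = [
            any(s <= p.start and p.end <= e for s, e in exons_by_gene[p.source_gene])
            for p in gene_probes.itertuples(index=False)
        ]
        assert all(contained) == expect_contained
        if not expect_contained:
            assert not any(contained)

    def test_probe_count_conservation(self, small_study, small_config):
        probes = small_study["probes"]
        n_bg = int(probes["is_background"].sum())
        assert n_bg == small_config.n_background_probes
        lo, hi = small_config.probes_per_gene
        per_gene = probes[~probes["is_background"]].groupby("source_gene").size()
        assert per_gene.between(lo, hi).all()
        assert len(per_gene) == len(small_study["gene_models"].genes)


class TestExpression:
    def test_within_module_correlation_calibrated(self, small_config):
        cfg = small_sim_config(seed=5)
        cfg.within_module_cor = 0.99
        cfg.noise_sd = 0.05
        cfg.probe_noise_sd = 0.02  # isolate the gene-level calibration
        gm, truth = generate_gene_models(cfg)
        probes = generate_probes(gm, cfg)
        intens, meta = simulate_expression(gm, truth, probes, cfg)
        # gene-level reconstruction through probe means (probe noise small)
        log2 = np.log2(intens)
        module = truth.module_genes("M1")[:15]
        vals = []
        for g in module:
            pid = probes.loc[probes["source_gene"] == g, "probe_id"]
            vals.append(log2.loc[pid].mean(axis=0).to_numpy())
        c = np.corrcoef(np.vstack(vals))
        iu = np.triu_indices(len(vals), 1)
        assert np.abs(c[iu]).mean() >= 0.95

    def test_low_variance_genes_flat_by_construction(self, small_study):
        truth = small_study["ground_truth"]
        probes = small_study["probes"]
        log2 = np.log2(small_study["intensities"])
        lowvar = truth.filter_fail.loc[
            truth.filter_fail["reason"] == "low_variance", "gene_id"
        ]
        for g in lowvar:
            pid = probes.loc[probes["source_gene"] == g, "probe_id"]
            gene_profile = log2.loc[pid].mean(axis=0)
            assert gene_profile.std(ddof=1) < 0.5

    def test_cross_module_correlation_below_within(self, small_study):
        truth = small_study["ground_truth"]
        probes = small_study["probes"]
        log2 = np.log2(small_study["intensities"])

        def gene_vec(g):
            pid = probes.loc[probes["source_gene"] == g, "probe_id"]
            return log2.loc[pid].mean(axis=0).to_numpy()

        m1 = [gene_vec(g) for g in truth.module_genes("M1")[:10]]
        m2 = [gene_vec(g) for g in truth.module_genes("M2")[:10]]
        within = np.corrcoef(np.vstack(m1))
        iu = np.triu_indices(10, 1)
        cross = np.corrcoef(np.vstack(m1), np.vstack(m2))[:10, 10:]
        assert np.abs(cross).mean() < np.abs(within[iu]).mean()

    def test_single_subset_design_is_legal(self):
        cfg = small_sim_config()
        cfg.sample_design = [("bone_marrow", "preB1", "D1"), ("bone_marrow", "preB1", "D2")]
        gm, truth = generate_gene_models(cfg)
        probes = generate_probes(gm, cfg)
        intens, meta = simulate_expression(gm, truth, probes, cfg)
        assert list(meta["subset"]) == ["preB1", "preB1"]
        assert intens.shape[1] == 2


class TestFacs:
    def test_separable_marker_single_threshold(self, small_config):
        events, labels = simulate_facs(small_config, "bone_marrow")
        cd34 = events["CD34"].to_numpy()
        is_preb1 = (labels == "preB1").to_numpy()
        thr = np.exp(2.0)  # between the low and high lognormal locations
        assert ((cd34 >= thr) == is_preb1).mean() == 1.0

    def test_zero_events(self):
        cfg = small_sim_config()
        cfg.n_facs_events = 0
        events, labels = simulate_facs(cfg, "tonsil")
        assert len(events) == 0 and len(labels) == 0

    def test_determinism(self, small_config):
        e1, l1 = simulate_facs(small_config, "bone_marrow")
        e2, l2 = simulate_facs(small_sim_config(), "bone_marrow")
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_series_equal(l1, l2)

    def test_missing_marker_params_rejected(self):
        cfg = small_sim_config()
        params = {k: dict(v) for k, v in cfg.facs_params.items()}
        del params[("bone_marrow", "preB1")]["CD34"]
        cfg.facs_params = params
        with pytest.raises(ValueError, match="missing marker"):
            simulate_facs(cfg, "bone_marrow")

    def test_unknown_tissue_rejected(self, small_config):
        with pytest.raises(ValueError, match="unknown tissue"):
            simulate_facs(small_config, "spleen")


def test_six_biotype_classes_only(small_study):
    assert set(small_study["gene_models"].genes["biotype"]) <= set(BIOTYPES)
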