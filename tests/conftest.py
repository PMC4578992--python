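import numpy as np
import pandas as pd
import pytest

from lncbcell import coexnet
from lncbcell.models import GeneModelSet
from lncbcell.pipeline import PipelineConfig, run_pipeline
from lncbcell.synthetic_data import SimulationConfig, simulate_study


def small_sim_config(seed: int = 3) -> SimulationConfig:
    """A miniature study: same structure as the default, minutes -> seconds."""
    return SimulationConfig(
        seed=seed,
        n_genes_per_biotype={
            "protein_coding": 120,
            "lincRNA": 30,
            "antisense": 20,
            "small_ncRNA": 10,
            "other_lncRNA": 5,
            "pseudogene": 40,
        },
        genes_per_module=(24, 16, 12, 10, 8, 6, 6),
        n_antisense_pairs=6,
        n_linc_mrna_pairs=6,
        n_mrna_mrna_pairs=6,
        n_control_pairs=4,
        n_low_expression_genes=6,
        n_low_variance_genes=6,
        probes_per_gene=(6, 10),
        n_background_probes=200,
        n_facs_events=600,
    )


@pytest.fixture(scope="session")
def small_config():
    return small_sim_config()


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_pipeline_report(tmp_path_factory):
    cfg = PipelineConfig(
        seed=3,
        outdir=tmp_path_factory.mktemp("smallrun"),
        simulation=small_sim_config(),
        n_background_draws=60,
        network=coexnet.NetworkConfig(min_module_size=5),
        write_outputs=True,
    )
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def default_pipeline_report(tmp_path_factory):
    """One full-size run (the study conditions) shared by the recovery tests."""
    cfg = PipelineConfig(
        seed=11, outdir=tmp_path_factory.mktemp("fullrun"), write_outputs=False
    )
    return run_pipeline(cfg)


def toy_gene_models() -> GeneModelSet:
    """Two chromosomes, overlapping antisense pair, spliced gene."""
    genes = pd.DataFrame(
        [
            ("gA", "chr1", 100, 1100, "+", "protein_coding"),
            ("gB", "chr1", 400, 900, "-", "antisense"),  # inside gA, opposite strand
            ("gC", "chr1", 5000, 8000, "+", "lincRNA"),  # spliced
            ("gD", "chr2", 0, 600, "-", "pseudogene"),
        ],
        columns=["gene_id", "chrom", "start", "end", "strand", "biotype"],
    )
    transcripts = pd.DataFrame(
        [("gA.t1", "gA"), ("gB.t1", "gB"), ("gC.t1", "gC"), ("gC.t2", "gC"), ("gD.t1", "gD")],
        columns=["transcript_id", "gene_id"],
    )
    exons = pd.DataFrame(
        [
            ("gA.t1", "chr1", 100, 1100, "+"),
            ("gB.t1", "chr1", 400, 900, "-"),
            ("gC.t1", "chr1", 5000, 5400, "+"),
            ("gC.t1", "chr1", 6000, 8000, "+"),
            ("gC.t2", "chr1", 5000, 5400, "+"),
            ("gD.t1", "chr2", 0, 600, "-"),
        ],
        columns=["transcript_id", "chrom", "start", "end", "strand"],
    )
    return GeneModelSet(genes, transcripts, exons)


@pytest.fixture
def gene_models_toy():
    return toy_gene_models()


def make_probe(probe_id, chrom, start, strand, gc=0.5, background=False):
    return {
        "probe_id": probe_id,
        "chrom": chrom,
        "start": start,
        "end": start + 25,
        "strand": strand,
        "gc_fraction": gc,
        "is_background": background,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
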