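import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from editome import (
    GeneModels,
    SimulationConfig,
    simulate_annotation,
    simulate_cohort,
    simulate_fixture,
)

settings.register_profile(
    "fixed",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_edit_sites=150, n_snp_sites=25, n_error_sites=25)


@pytest.fixture(scope="session")
def sim(small_config):
    """(annotation, cohort) for the shared small synthetic cohort."""
    rng = np.random.default_rng(small_config.seed)
    ann = simulate_annotation(small_config, rng)
    cohort = simulate_cohort(small_config, ann, rng)
    return ann, cohort


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_config):
    """(annotation, cohort, paths) for the same cohort written to disk."""
    out = tmp_path_factory.mktemp("fixture")
    return simulate_fixture(small_config, out)


@pytest.fixture()
def tiny_gene_models():
    """Two plus-strand and one minus-strand gene, plus a both-strand overlap.

    chr1: GA+ [100, 700] (exons 100-300 / 500-700, intron 301-499)
          GB- [1000, 1600] (exons 1000-1200 / 1400-1600)
          GC+ and GD- overlapping on [2000, 2400] (single exons)
    """
    genes = pd.DataFrame(
        [
            ("GA", "chr1", 100, 700, "+", "protein_coding"),
            ("GB", "chr1", 1000, 1600, "-", "protein_coding"),
            ("GC", "chr1", 2000, 2400, "+", "protein_coding"),
            ("GD", "chr1", 2000, 2400, "-", "protein_coding"),
        ],
        columns=["gene_id", "chrom", "start", "end", "strand", "biotype"],
    )
    features = pd.DataFrame(
        [
            ("GA", "chr1", 100, 300, "exon"),
            ("GA", "chr1", 500, 700, "exon"),
            ("GA", "chr1", 100, 300, "CDS"),
            ("GA", "chr1", 500, 700, "3'UTR"),
            ("GB", "chr1", 1000, 1200, "exon"),
            ("GB", "chr1", 1400, 1600, "exon"),
            ("GB", "chr1", 1000, 1200, "3'UTR"),
            ("GB", "chr1", 1400, 1600, "CDS"),
            ("GC", "chr1", 2000, 2400, "exon"),
            ("GC", "chr1", 2000, 2400, "CDS"),
            ("GD", "chr1", 2000, 2400, "exon"),
            ("GD", "chr1", 2000, 2400, "CDS"),
        ],
        columns=["gene_id", "chrom", "start", "end", "kind"],
    )
    return GeneModels(genes, features)
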