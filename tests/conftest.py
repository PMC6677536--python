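import numpy as np
import pytest

from pictseq import AnalysisParameters, build_genome_bundle


@pytest.fixture(scope="session")
def params():
    return AnalysisParameters()


@pytest.fixture(scope="session")
def small_params():
    # narrow flank so small chromosomes can host insertions
    return AnalysisParameters(metaplot_flank=500)


@pytest.fixture(scope="session")
def small_bundle(small_params):
    """Tiny exact-copy bundle (divergence 0) shared by read-level tests."""
    return build_genome_bundle(
        small_params,
        n_chrom=2,
        chrom_len=30_000,
        n_families=3,
        copies_per_family=2,
        divergence=0.0,
        seed=11,
        te_len=800,
        n_genes=6,
        gene_len=600,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
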