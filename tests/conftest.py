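import numpy as np
import pytest

from caretaker.synthetic_data import CloneDatasetSpec, GenomeSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genome_spec():
    return GenomeSpec(
        n_genes=200,
        n_hrpg=20,
        arm_names=("2L", "2R"),
        arm_length_bp=(1_000_000, 1_500_000),
        mean_gene_length_bp=1_500,
        seed=7,
    )


@pytest.fixture
def loser_spec():
    return CloneDatasetSpec(genotype_label="loser", n_discs=47,
                            elimination_strength=0.95, noise_sd=0.1, seed=11)


@pytest.fixture
def rescue_spec():
    return CloneDatasetSpec(genotype_label="rescued", n_discs=45,
                            elimination_strength=0.05, noise_sd=0.1, seed=13)
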