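import pytest

from exonbias import (
    MultiGroup,
    PairedTwoGroup,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def paired_dataset():
    """Small noisy paired two-group dataset with differential expression."""
    cfg = SimulationConfig(
        n_genes=40,
        exons_per_gene=4,
        design=PairedTwoGroup(n_pairs=5),
        frac_de_genes=0.3,
        seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Noise-free, background-free dataset: probes follow t*f exactly."""
    cfg = SimulationConfig(
        n_genes=30,
        exons_per_gene=4,
        design=PairedTwoGroup(n_pairs=5),
        frac_de_genes=0.5,
        noise_sd_log=0.0,
        background_mean=0.0,
        background_sd=0.0,
        seed=3,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def multigroup_dataset():
    """Six-tissue, three-replicate dataset for the unpaired analyses."""
    cfg = SimulationConfig(
        n_genes=30,
        exons_per_gene=4,
        design=MultiGroup(n_groups=6, n_replicates=3),
        frac_de_genes=0.3,
        seed=5,
    )
    return simulate_dataset(cfg)
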