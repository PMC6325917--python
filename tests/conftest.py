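import pytest

from fbfsubnet.annotation import GeneIndex
from fbfsubnet.synthetic_data import (SyntheticConfig, generate_transcriptome,
                                      simulate_study)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_genes=80, library_size=10_000, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One complete small synthetic study, shared across tests."""
    genes, genome, truth = generate_transcriptome(small_config)
    samples = simulate_study(small_config, truth, genes)
    return {
        "config": small_config,
        "genes": genes,
        "genome": genome,
        "truth": truth,
        "samples": samples,
        "index": GeneIndex(genes),
    }
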