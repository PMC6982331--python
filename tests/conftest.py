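import numpy as np
import pytest

from circjkit.synthetic import SimConfig, simulate_genome_annotation, simulate_reads


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=7, n_background_reads=300)


@pytest.fixture(scope="session")
def small_fixture(small_config):
    """One shared synthetic dataset: (genome, exons, truth, reads, planted)."""
    genome, exons, truth = simulate_genome_annotation(small_config)
    reads, planted = simulate_reads(genome, truth, small_config)
    return genome, exons, truth, reads, planted


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
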