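import pytest

from phagemosaic.synthetic_data import SimConfig, emit_genome_sequences, simulate_population


@pytest.fixture(scope="session")
def sep_population():
    """A well-separated synthetic population (4 clusters x 5 genomes, seed 1)."""
    config = SimConfig(seed=1)
    genomes, genes, truth = simulate_population(config)
    return config, genomes, genes, truth


@pytest.fixture(scope="session")
def sep_sequences(sep_population):
    """The same population with emitted nucleotide sequences and host."""
    config, genomes, genes, truth = sep_population
    genomes_seq, host = emit_genome_sequences(genomes, truth, config)
    return config, genomes_seq, genes, truth, host
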