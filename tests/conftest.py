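import pytest

from tigkit.fixtures import random_genome, random_pangenome

FIG1A_STRINGS = ["TTCTGA", "GTCTGT"]  # two strings sharing a 4-mer core


@pytest.fixture
def fig1a():
    return FIG1A_STRINGS


@pytest.fixture
def small_genomes():
    """Ten deterministic length-20 genomes."""
    return [random_genome(seed, 20) for seed in range(10)]


@pytest.fixture
def small_pangenome():
    return random_pangenome(3, 30, 3, 0.1)
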