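import pytest

from rnpscan.synthetic import make_planted_genomes, make_toy_library


@pytest.fixture(scope="session")
def toy_library():
    """The shared two-subfamily toy model library (built once per session)."""
    return make_toy_library(seed=1)


@pytest.fixture(scope="session")
def small_planted_genomes(toy_library):
    """Six 20 kb genomes with one planted gene each (mixed strands)."""
    return make_planted_genomes(toy_library, 6, genome_length=20_000, seed=11)
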