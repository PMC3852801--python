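import numpy as np
import pytest

from pyroerr.ace import Assembly, PaddedContig, PaddedRead, PairwiseAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def padded_fixture_assembly():
    """The three-read normalization scenario: R3 carries an extra C, so the
    consensus and the other reads are padded at that column."""
    reads = (
        PaddedRead("R1", "AAGGCC-GTT", 1),
        PaddedRead("R2", "GGCC-GTTGCG", 3),
        PaddedRead("R3", "CCCGTTGCGGC", 5),
    )
    return Assembly((PaddedContig("c1", "AAGGCC-GTTGCGGC", reads),), source="fixture")


@pytest.fixture
def context_example():
    """Alignment whose gap contexts are AA, CCCCC, AA, T, GG and T."""
    return PairwiseAlignment(template="AACCCCCAATG-TAT", read="-AC--CC---GGTG-")


@pytest.fixture
def small_simulation():
    """A modest seeded synthetic assembly shared by integration tests."""
    from pyroerr.simulate import SimulationParams, simulate_assembly

    params = SimulationParams(genome_length=20_000, coverage=10, seed=99)
    return simulate_assembly(params)
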