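import pytest

from oysterlsu.covariation import RnaAlignment
from oysterlsu.synthetic import (
    SimConfig,
    demo_structure,
    simulate_genome,
    simulate_structured_alignment,
)


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def synthetic_genome(default_config):
    genome, truth = simulate_genome(default_config)
    return genome, truth


@pytest.fixture(scope="session")
def truth_structure():
    return demo_structure()


@pytest.fixture(scope="session")
def structured_alignment(truth_structure):
    return simulate_structured_alignment(
        truth_structure, n_seqs=100, pair_sub_rate=0.8, bg_sub_rate=0.1, seed=1
    )


def make_alignment(*rows):
    return RnaAlignment(
        ids=tuple(f"s{i}" for i in range(len(rows))), rows=tuple(rows)
    )
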