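import numpy as np
import pytest

from pienet.mm import unit_pair_table
from pienet.synthetic import GeneratorConfig, generate_toy_complex


@pytest.fixture(scope="session")
def toy():
    """Small deterministic duplex+peptide complex with 10 snapshots."""
    return generate_toy_complex(GeneratorConfig(n_snapshots=10, seed=42))


@pytest.fixture(scope="session")
def toy_mm_table(toy):
    return unit_pair_table(toy.system, toy.segments, toy.rules)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
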