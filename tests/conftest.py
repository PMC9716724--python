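import numpy as np
import pytest

from pandanet.config import Locus, SimConfig, default_loci
from pandanet.relatedness import AlleleFrequencyTable


@pytest.fixture
def small_config() -> SimConfig:
    """A fast, small population: ~15-25 residents in two generations."""
    return SimConfig(
        n_founders=8,
        n_generations=2,
        immigrant_females_per_gen=2,
        n_surveys=4,
        seed=123,
    )


@pytest.fixture(scope="session")
def panel() -> tuple[Locus, ...]:
    return default_loci()


@pytest.fixture(scope="session")
def panel_freqs(panel) -> AlleleFrequencyTable:
    return AlleleFrequencyTable.from_loci(panel)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
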