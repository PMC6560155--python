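import numpy as np
import pytest

from aarratio import (
    ScenarioConfig,
    StandardWeights,
    StratifiedCountTable,
    make_population,
    simulate_scenario,
)
from aarratio.simulation import DEFAULT_WEIGHTS


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_table():
    """Hand-sized 3 regions x 2 age strata."""
    return StratifiedCountTable(
        ["A", "B", "C"],
        ["young", "old"],
        counts=[[5, 10], [8, 3], [0, 4]],
        population=[[10_000, 20_000], [15_000, 10_000], [8_000, 12_000]],
    )


@pytest.fixture
def toy_weights():
    return StandardWeights([0.6, 0.4], ["young", "old"])


@pytest.fixture(scope="session")
def pop120():
    """The synthetic 120-county study region (10x12 rook lattice)."""
    return make_population(seed=7)


@pytest.fixture(scope="session")
def weights5():
    return StandardWeights(np.array(DEFAULT_WEIGHTS))


@pytest.fixture(scope="session")
def t1_result(pop120):
    """A small stack of T1 replicates at the common-disease total."""
    config = ScenarioConfig.standard("T1", "medium", total_count=13_000.0,
                                     n_replicates=20, seed=11)
    return simulate_scenario(pop120, config)
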