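import numpy as np
import pytest

from betadfc import (
    PATHOLOGICAL_COUPLING,
    SimulationConfig,
    compute_metrics,
    simulate,
)


@pytest.fixture(scope="session")
def pathological_run():
    """One unstimulated pathological run on the default 3 s / 0.1 ms grid."""
    return simulate(SimulationConfig(seed=1), coupling=PATHOLOGICAL_COUPLING)


@pytest.fixture(scope="session")
def pathological_metrics(pathological_run):
    return compute_metrics(pathological_run)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
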