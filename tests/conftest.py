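import numpy as np
import pytest

from polledsim import ScenarioConfig

#: One suite-wide seed so every stochastic check is reproducible.
SUITE_SEED = 20210211


@pytest.fixture
def rng():
    return np.random.default_rng(SUITE_SEED)


@pytest.fixture
def tiny_cfg():
    """A desk-scale configuration for fast integration runs."""
    return ScenarioConfig(scheme="A", years=5, replicates=2, seed=SUITE_SEED).scaled(0.05)
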