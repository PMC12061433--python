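import numpy as np
import pytest

from tcburst.simulator import Recording, RunConfig, run


@pytest.fixture(scope="session")
def short_baseline() -> Recording:
    """A 5 s baseline-drive run shared across invariant tests."""
    return run(RunConfig(duration=5000.0, seed=11))


@pytest.fixture(scope="session")
def short_rivalry() -> Recording:
    """A 12 s rivalry run shared across dominance/analysis tests."""
    from tcburst.experiments import rivalry_config
    return run(rivalry_config((1400.0, 1400.0), 12000.0, seed=5))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
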