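import numpy as np
import pytest

from stngpe import IntegratorConfig, LoopParams


@pytest.fixture(scope="session")
def endogenous():
    """Strong-coupling parameterization with sustained beta oscillations."""
    return LoopParams.endogenous()


@pytest.fixture(scope="session")
def exogenous():
    """Weak-coupling, entrainable parameterization."""
    return LoopParams.exogenous()


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def short_cfg():
    return IntegratorConfig(dt=0.1, duration=1000.0)
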