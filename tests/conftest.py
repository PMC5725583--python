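import numpy as np
import pytest
from hypothesis import settings

from genostore.model import EnvironmentalRegime

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def regime_c10():
    """The reference deterministic-analysis regime."""
    return EnvironmentalRegime(s_max=0.1, period=10, p=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260)
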