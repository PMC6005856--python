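import numpy as np
import pytest
from hypothesis import settings

from mcfi.cohort_sim import default_groups
from mcfi.fi_core import default_catalog

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def groups():
    """The four shipped group calibrations (calibrated once per session)."""
    return default_groups()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
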