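import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ubcsim import (off_cell_params, on_cell_params,  # noqa: E402
                    ampa_receptor_params, mglur2_receptor_params)


@pytest.fixture(scope="session")
def on_cell():
    return on_cell_params()


@pytest.fixture(scope="session")
def off_cell():
    return off_cell_params()


@pytest.fixture(scope="session")
def ampa():
    return ampa_receptor_params()


@pytest.fixture(scope="session")
def mglur2():
    return mglur2_receptor_params()


@pytest.fixture(scope="session")
def leak_only_on(on_cell):
    return on_cell.with_gmax(Na=0.0, K=0.0, K_slow=0.0, H=0.0)


@pytest.fixture(scope="session")
def leak_only_off(off_cell):
    return off_cell.with_gmax(Na=0.0, K=0.0, K_slow=0.0, H=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230915)
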