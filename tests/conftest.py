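import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def slab_geometry():
    from fanomc import slab
    return slab()


@pytest.fixture(scope="session")
def chamber_geometry():
    from fanomc import chamber_like
    return chamber_like()


@pytest.fixture(scope="session")
def diode_geometry():
    from fanomc import diode_like
    return diode_like()
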