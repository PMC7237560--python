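import numpy as np
import pytest
from hypothesis import settings

import microdosim as md

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lu177():
    return md.build_radionuclide("lu177")


@pytest.fixture(scope="session")
def tb161():
    return md.build_radionuclide("tb161")


@pytest.fixture(scope="session")
def water_table():
    return md.default_stopping_power_table()


@pytest.fixture(scope="session")
def kernel(water_table):
    return md.build_kernel(water_table)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
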