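import numpy as np
import pytest

from girkflow import GeometryParams, default_parameters


@pytest.fixture(scope="session")
def gi_params():
    return default_parameters("Gi-coupled")


@pytest.fixture(scope="session")
def gs_params():
    return default_parameters("Gs-coupled")


@pytest.fixture(scope="session")
def geometry():
    return GeometryParams()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)
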