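import pytest

from ncrfit import RouteRegistry, ThermoContext, bundled_constants


@pytest.fixture(scope="session")
def registry():
    return RouteRegistry()


@pytest.fixture(scope="session")
def ctx():
    return ThermoContext()


@pytest.fixture(scope="session")
def constants():
    return bundled_constants()
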