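import pytest

from gelprint.synthetic import reference_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """Reference parameter bundle (gels, support bath, hardware, geometry)."""
    return reference_fixtures()


@pytest.fixture(scope="session")
def gels(fixtures):
    return fixtures.gels


@pytest.fixture(scope="session")
def default_system(fixtures):
    return fixtures.system


@pytest.fixture(scope="session")
def hardware(fixtures):
    return fixtures.hardware
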