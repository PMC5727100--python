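import pytest

from acylsugar import synth
from acylsugar.residues import default_scheme


@pytest.fixture(scope="session")
def fixtures():
    """The four synthetic ortholog stand-in sequences."""
    return synth.make_reference_fixtures()


@pytest.fixture(scope="session")
def asat2_scheme():
    return default_scheme("ASAT2")


@pytest.fixture(scope="session")
def asat3_scheme():
    return default_scheme("ASAT3")
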