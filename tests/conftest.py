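import pytest

from tdckit.msa import ScoringScheme
from tdckit.signatures import load_signatures


@pytest.fixture(scope="session")
def sigs():
    return load_signatures()


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()
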