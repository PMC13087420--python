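import pytest
from hypothesis import settings

from smnvar.cohort import make_scenario
from smnvar.refmodel import TranscriptModel

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scenario():
    """The bundled SMN-like demo scenario (deterministic, seed 7)."""
    return make_scenario(7)


@pytest.fixture(scope="session")
def smn1(scenario):
    return scenario.smn1


@pytest.fixture(scope="session")
def smn2(scenario):
    return scenario.smn2


@pytest.fixture
def toy_model():
    """Minimal transcript: CDS 1-18 encoding MARRH, 6-nt 3'UTR."""
    return TranscriptModel(
        id="toy",
        sequence="ATGGCTAGAAGGCATTGAATAAGG",
        cds_start=1,
        cds_end=18,
        exons=((1, 24),),
    )
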