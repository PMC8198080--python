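import pytest

from cubkit.sequence_io import CodingSequence


@pytest.fixture
def minimal_cds() -> CodingSequence:
    return CodingSequence(id="x", species="toy", bases="ATGGCAGAATAA")


@pytest.fixture(scope="session")
def published_rscu():
    from cubkit.resources import load_published_rscu

    return load_published_rscu()


@pytest.fixture(scope="session")
def species_rscu(published_rscu):
    from cubkit.resources import SPECIES

    return [published_rscu[s] for s in SPECIES]
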