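import pytest
from hypothesis import HealthCheck, settings

from geoharvest import fixtures, transport

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """A small offline corpus shared by the unit tests: 12 GEO + 6 AE
    fixtures with mirrors and SuperSeries containers."""
    root = tmp_path_factory.mktemp("corpus")
    index = fixtures.generate_corpus(root, seed=7, n_geo=12, n_ae=6,
                                     mirror_fraction=0.4,
                                     superseries_fraction=0.25)
    return root, index


@pytest.fixture()
def fetcher(corpus):
    return transport.open_fetcher(corpus[0])
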