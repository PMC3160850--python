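import numpy as np
import pytest

from fragpick import fixtures
from fragpick.fixtures import FixtureSpec, PlantedQuery


@pytest.fixture(scope="session")
def planted_world():
    """A 50-chunk synthetic database containing one exact copy of the query
    chunk, plus the query built from that copy (noise-free predictors)."""
    spec = FixtureSpec(seed=11, n_chunks=50, chunk_length_range=(30, 60),
                       planted_queries=[PlantedQuery(length=40)])
    chunks, truth = fixtures.generate_vall(spec)
    planted = truth["planted_chunks"][0]
    query = fixtures.query_from_chunk(planted)
    return chunks, planted, query, truth


@pytest.fixture(scope="session")
def tiny_world():
    """A small 12-chunk database for fast behavioral tests."""
    spec = FixtureSpec(seed=5, n_chunks=12, chunk_length_range=(22, 34),
                       planted_queries=[PlantedQuery(length=30)])
    chunks, truth = fixtures.generate_vall(spec)
    planted = truth["planted_chunks"][0]
    query = fixtures.query_from_chunk(planted)
    return chunks, planted, query, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
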