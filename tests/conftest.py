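import logging

import pytest

from latentpath.fba import apply_curations
from latentpath.fixtures import FixtureSpec, build_core_model
from latentpath.network import add_currency_exchanges, prune_for_search

logging.getLogger("latentpath").setLevel(logging.ERROR)
logging.getLogger("latentpath.fba").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def core_model():
    return build_core_model()


@pytest.fixture(scope="session")
def rubp_model():
    return build_core_model(FixtureSpec(include_rubp=True))


@pytest.fixture(scope="session")
def prepared_model(core_model):
    """Core model pruned to cytosolic reactions and currency-augmented."""
    return add_currency_exchanges(prune_for_search(core_model))


@pytest.fixture(scope="session")
def prepared_rubp_model(rubp_model):
    return add_currency_exchanges(prune_for_search(rubp_model))


@pytest.fixture(scope="session")
def curated_model(core_model):
    return apply_curations(core_model)
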