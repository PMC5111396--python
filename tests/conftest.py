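import pytest
from hypothesis import settings

import picogem as pg

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy():
    return pg.make_toy_photoautotroph()


@pytest.fixture(scope="session")
def medium():
    return pg.default_medium()


@pytest.fixture(scope="session")
def toy_comp(toy):
    return toy.toy_composition


@pytest.fixture(scope="session")
def toy_base(toy):
    """Toy model without its biomass/maintenance reactions, for the
    biomass-analytics entry points that install their own."""
    base = toy.copy()
    base.reactions.pop("BOF")
    base.reactions.pop("NGAM")
    base.objective_id = ""
    return base
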