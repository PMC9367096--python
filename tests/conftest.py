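import pytest

from fluxdesign.design import GdlsConfig
from fluxdesign.synthetic import ToyModelSpec, purine_core_model, random_toy_model


@pytest.fixture
def purine_core():
    return purine_core_model()


@pytest.fixture
def gdls_cfg():
    """Global (unbounded-neighbourhood) GDLS configuration for the fixture."""
    return GdlsConfig(
        outer_objective_id="DM_imp",
        inner_objective_id="BIOMASS",
        max_knockouts=2,
        min_growth=0.05,
        neighborhood_size=None,
        search_paths=2,
    )


def make_toy(seed: int, n_extra: int = 5, **kw):
    return random_toy_model(ToyModelSpec(n_extra_reactions=n_extra, seed=seed, **kw))
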