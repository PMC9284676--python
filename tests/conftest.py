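import pytest
from hypothesis import HealthCheck, settings

from repeatome_kit import SimulationConfig, parse_newick, simulate_repeatome

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def balanced4():
    """Rooted ultrametric 4-tip tree with two cherries."""
    return parse_newick("((s01:0.3,s02:0.3):0.7,(s03:0.5,s04:0.5):0.5);")


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic comparative-clustering dataset at default conditions."""
    return simulate_repeatome(SimulationConfig(tree_seed=3, data_seed=4))
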