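import numpy as np
import pytest

from pdgsim import climate
from pdgsim.engine import ScenarioConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def base_series():
    """The standard 5-year synthetic weather block, reference elevation 1200 m."""
    return climate.generate_base_series(5, 1)


@pytest.fixture
def desk_config():
    """A small but fully featured scenario configuration for end-to-end tests."""
    return ScenarioConfig.for_scenario(
        "B",
        n_founders=80,
        n_generations=2,
        n_preevolution=1,
        n_repetitions=1,
        max_population=200,
    )
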