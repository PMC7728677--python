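import dendropy
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from safusion.markov import KaryoState, RateParams, build_state_space

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def space():
    return build_state_space(6, 12)


@pytest.fixture
def rates():
    return RateParams(delta=1.0, gamma=0.8, sigma=0.5, rho=2.0)


@pytest.fixture
def three_taxon_tree():
    return dendropy.Tree.get(data="((A:0.3,B:0.5):0.4,C:0.9);",
                             schema="newick")


@pytest.fixture
def three_taxon_tips():
    return {
        "A": KaryoState(8, "XY"),
        "B": KaryoState(10, "neoXY"),
        "C": KaryoState(12, "XY"),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
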