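import numpy as np
import pytest

from mesowm import ModelParameters, paper_defaults


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return paper_defaults()


@pytest.fixture(scope="session")
def bistable_fixed_points(params):
    """The fixed-point triple at baseline releasability W34 = 0.36."""
    from mesowm import find_fixed_points

    return find_fixed_points(0.36, params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
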