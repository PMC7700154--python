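import numpy as np
import pytest

from movscreen.synthdata import generate_library, make_ranked_fixture


@pytest.fixture(scope="session")
def small_library():
    """60 deterministic synthetic molecules shared across tests."""
    return generate_library(60, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def worked_ranked_lists():
    """The three constructed 772-compound, 14-active lists with 4/3/2
    actives inside the top ceil(0.01*772)=8 positions."""
    tail = list(range(100, 110))
    return {
        4: make_ranked_fixture(772, 14, [1, 2, 3, 5] + tail),
        3: make_ranked_fixture(772, 14, [1, 2, 5] + tail + [200]),
        2: make_ranked_fixture(772, 14, [1, 5] + tail + [200, 300]),
    }
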