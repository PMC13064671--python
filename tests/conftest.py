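import numpy as np
import pytest

from beadweb import InteractionParameters


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def two_type_pair_only_params():
    """Two types where only the mixed pair grows (reference pair, G = 1)."""
    def make(f_first: float) -> InteractionParameters:
        return InteractionParameters(
            growth_single=np.array([0.0, 0.0]),
            growth_pair=np.array([[0.0, 1.0], [1.0, 0.0]]),
            fraction_pair=np.array([[1.0, f_first], [1.0 - f_first, 1.0]]),
        )

    return make


def random_proportions(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.dirichlet(np.ones(n))
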