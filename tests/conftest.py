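import numpy as np
import pytest

from opinioncusp.meanfield import sample_uniform_composition


@pytest.fixture(scope="session")
def random_compositions():
    """100 flat-simplex compositions shared by the oracle-equivalence and
    invariance tests."""
    rng = np.random.default_rng(20240901)
    return sample_uniform_composition(rng, 100)


@pytest.fixture
def negative_lean():
    from opinioncusp.experiments import FIXTURES

    return FIXTURES["negative-lean"].composition
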