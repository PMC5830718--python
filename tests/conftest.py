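import numpy as np
import pytest

import anoht


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def iris_std():
    """Standardized Iris features with species labels."""
    return anoht.iris_fixture(standardize=True)


@pytest.fixture(scope="session")
def two_part_spec():
    """The canonical gapped mixture: equal-weight U(0,1) and U(3,4)."""
    return anoht.MixtureSpec(parts=((0, 1, 0.5), (3, 4, 0.5)), n=400)
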