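import numpy as np
import pytest

from effdim.sampling import build_design


@pytest.fixture(scope="session")
def design_k2():
    """Shared N=2^12, k=2 design with pair matrices."""
    return build_design(2 ** 12, 2, subset_orders=(2,))


@pytest.fixture(scope="session")
def design_k3():
    """Shared N=2^13, k=3 design with pair and triplet matrices."""
    return build_design(2 ** 13, 3, subset_orders=(2, 3))


@pytest.fixture()
def rng():
    return np.random.default_rng(20221019)
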