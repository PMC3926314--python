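import numpy as np
import pytest


@pytest.fixture
def rng():
    """Seeded generator shared by randomized tests."""
    return np.random.default_rng(12345)


@pytest.fixture
def worked_window():
    """The 3×3 window whose horizontal pair counts are known by hand."""
    return np.array([[0, 0, 1], [0, 1, 1], [0, 2, 2]])
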