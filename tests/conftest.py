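import numpy as np
import pytest

from shallowcna.grid import build_grid


@pytest.fixture
def two_chrom_grid():
    """Two small chromosomes (10 and 8 full 1 Mb bins)."""
    return build_grid([("chrA", 10_000_000), ("chrB", 8_500_000)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
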