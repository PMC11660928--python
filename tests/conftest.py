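import numpy as np
import pytest

from replitime import BinGrid, FractionProfile


@pytest.fixture
def small_grid():
    """Two chromosomes, 20 + 10 bins of 50 kb."""
    return BinGrid.from_chrom_sizes({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture
def one_chrom_grid():
    return BinGrid.from_chrom_sizes({"chr1": 1_000_000})


def make_profile(grid, D, **kwargs):
    kwargs.setdefault("stage", "smoothed")
    return FractionProfile(grid, np.asarray(D, dtype=float), **kwargs)
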