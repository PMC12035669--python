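import numpy as np
import pytest

from demark.genomic_io import BinnedTrack, ChromSizes
from demark.simdata import SimConfig, simulate_all


@pytest.fixture
def sizes():
    return ChromSizes({"chr1": 2_000_000, "chr2": 1_000_000})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(sizes, bin_size, rng, nan_frac=0.0, missing_policy="zero",
               low=0.0, high=10.0):
    values = {}
    for chrom in sizes:
        n = sizes.n_bins(chrom, bin_size)
        v = rng.uniform(low, high, n)
        if nan_frac > 0:
            v[rng.random(n) < nan_frac] = np.nan
        values[chrom] = v
    return BinnedTrack(sizes, bin_size, values, missing_policy=missing_policy)


@pytest.fixture(scope="session")
def sim_default():
    """One full synthetic epigenome at the default study conditions,
    shared by the recovery tests (generation only; every check recomputes
    its own statistics)."""
    return simulate_all(SimConfig(seed=1))
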