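import numpy as np
import pytest

from hicontacts import HiCMap, Region, SyntheticSpec, generate_map


@pytest.fixture
def small_map():
    """Deterministic 5x5 symmetric map for direct read-off tests."""
    m = np.array([
        [9, 1, 5, 0, 2],
        [1, 8, 4, 6, 1],
        [5, 4, 0, 3, 7],
        [0, 6, 3, 9, 2],
        [2, 1, 7, 2, 8],
    ], dtype=float)
    return HiCMap(chromosome="chr1", resolution=10_000, matrix=m)


@pytest.fixture
def null_map():
    """Null synthetic map, no planted signal, exact-model Weibull noise."""
    spec = SyntheticSpec(n_bins=300, seed=11, shape=2.0, lambda0=100.0, gamma=1.0)
    hic, _ = generate_map(spec, chromosome="chrN", resolution=10_000)
    return hic


def region_at_bin(b, resolution=10_000, chrom="chr1", name=None):
    r = Region(chrom, b * resolution, (b + 1) * resolution,
               name or f"bin{b}")
    return r.assign_bins(resolution)


@pytest.fixture
def make_region():
    return region_at_bin
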