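import numpy as np
import pytest
from hypothesis import settings

import velogrn as vg

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_truth():
    return vg.simulate_truth(n_tfs=10, n_genes=6, k_per_gene=2, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    """(expr, velo, peaks, sites, genes) at a size every test can afford."""
    return vg.simulate_data(small_truth, n_cells=120, seed=7)


def brute_force_coverage(site, intervals):
    """Per-basepair oracle for the overlap fraction S: walk every basepair
    of the site and count those inside any peak."""
    covered = 0
    for bp in range(site.start, site.end):
        if any(
            iv.chrom == site.chrom and iv.start <= bp < iv.end
            for iv in intervals
        ):
            covered += 1
    return covered / (site.end - site.start)
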