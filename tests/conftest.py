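import numpy as np
import pytest

import gepred as gp


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def markers_small():
    """20 genotypes x 60 markers, 0/1/2 coded."""
    return gp.simulate_markers(20, 60, seed=11)


@pytest.fixture()
def pheno_balanced(markers_small):
    """Balanced 3-environment design over the small panel (60 records)."""
    return gp.design_table(markers_small.genotype_ids, n_env=3, seed=11)


@pytest.fixture()
def kset_mds(markers_small, pheno_balanced):
    G = gp.gb_kernel(markers_small)
    return gp.build_ge_kernels(pheno_balanced, G, model="MDs")
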