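import numpy as np
import pytest

import jsseconn as jc


@pytest.fixture(scope="session")
def small_config():
    """An 8-region cohort small enough for fast end-to-end tests."""
    return jc.SimulationConfig(
        n_per_group=3, n_vox=60, n_regions=8,
        effect_pairs=[(0, 1)], effect_size=3.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return jc.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_network(small_cohort):
    return jc.build_connectome(small_cohort[0])


@pytest.fixture(scope="session")
def subject_90():
    """One full-sized subject: 90 regions, 200 voxels per region."""
    cfg = jc.SimulationConfig(n_per_group=2, n_vox=200, n_regions=90, seed=3)
    return jc.simulate_cohort(cfg)[0]


def random_binary_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    A = (rng.random((n, n)) < p).astype(np.int8)
    A = np.triu(A, 1)
    A = A + A.T
    return jc.BinaryGraph(adjacency=A, sparsity=float(A.sum() / (n * (n - 1))))
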