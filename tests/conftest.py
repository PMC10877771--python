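import numpy as np
import pytest

import clonetracer as ct


def make_clusters(spec, samples=("S1", "S2")):
    """Clusters from (label, size, median...) tuples; synthetic member ids."""
    out = []
    for label, size, *median in spec:
        members = tuple(f"{label}{i}" for i in range(size))
        out.append(ct.CloneCluster(label, tuple(samples), members,
                                   np.array(median, dtype=float)))
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 3-clone, 2-sample cohort with full ground truth."""
    return ct.simulate_cohort(K=3, S=2, n_snv_per_clone=60, depth=100,
                              purity=0.7, seed=11)


@pytest.fixture(scope="session")
def medium_cohort():
    """A 5-clone, 3-sample cohort at the emulated study's scale."""
    return ct.simulate_cohort(K=5, S=3, n_snv_per_clone=200, depth=100,
                              purity=0.7, seed=5)
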