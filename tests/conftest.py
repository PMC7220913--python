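import numpy as np
import pytest

from wmcpm.cohort import Cohort
from wmcpm.synth import SyntheticSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    return SyntheticSpec(n_participants=120, n_nodes=20, n_pos_edges=6,
                         n_neg_edges=6, effect_r=0.4, seed=7)


@pytest.fixture
def small_cohort(small_spec):
    cohort, truth = generate_cohort(small_spec)
    return cohort, truth


@pytest.fixture
def tiny_cohort(rng):
    """12 participants, 10 edges — small enough for brute-force oracles."""
    n, e = 12, 10
    edges = rng.standard_normal((n, e))
    gf = rng.normal(60, 8, size=n)
    return Cohort(ids=np.array([f"s{i}" for i in range(n)]), gf=gf, edges=edges,
                  mean_fd=np.abs(rng.normal(0.08, 0.02, size=n)), n_nodes=5)
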