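import numpy as np
import pytest

from wmnet.networks import NetworkPartition
from wmnet.simulate import CohortConfig, generate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def behavior_cohort():
    """Default-condition cohort, behaviour only (41 subjects, 4920 trials)."""
    return generate_cohort(CohortConfig.behavior_only(), master_seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced imaging cohort: 6 subjects, 120 ROIs, 12-node networks."""
    cfg = CohortConfig(n_subjects=6, n_rois=120, nodes_per_network=12)
    return generate_cohort(cfg, master_seed=7)


@pytest.fixture(scope="session")
def truth_partition(small_cohort):
    truth = small_cohort.truth
    return NetworkPartition(tuple(truth.maintenance_nodes),
                            tuple(truth.manipulation_nodes), 0.1)
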