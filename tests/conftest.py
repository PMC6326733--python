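import numpy as np
import pytest

from connsim.groundtruth import generate_groundtruth, generate_partition


@pytest.fixture(scope="session")
def small_partition():
    # 40 nodes, 4 modules named so module-targeted designs work
    return generate_partition(40, module_sizes={"DMN": 14, "FPN": 10, "DAN": 6, "Visual": 10})


@pytest.fixture(scope="session")
def small_groundtruth(small_partition):
    return generate_groundtruth(small_partition, n_timepoints=300, seed=7)


@pytest.fixture(scope="session")
def default_partition():
    return generate_partition(264, seed=0)


@pytest.fixture(scope="session")
def default_groundtruth(default_partition):
    return generate_groundtruth(default_partition, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
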