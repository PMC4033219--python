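import numpy as np
import pytest

from subgroupsim import SimulationDesign, simulate_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def design3():
    """Default three-group design cell with moderate separation."""
    return SimulationDesign(
        n_groups=3,
        total_n=150,
        group_separation_delta=0.5,
        subgroup_separation=0.10,
    )


@pytest.fixture
def train3(design3):
    train, _ = simulate_pair(design3, 7)
    return train


@pytest.fixture
def pair2():
    """Two-group pair with clear separation, handy for binary methods."""
    design = SimulationDesign(
        n_groups=2,
        total_n=100,
        group_separation_delta=0.8,
        subgroup_separation=0.05,
    )
    return simulate_pair(design, 11)
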