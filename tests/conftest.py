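import numpy as np
import pytest

from coraldemog.matrices import LifeTableSample
from coraldemog.synthdata import chagos_like_world, generate_recovery_fixture

WORLD_SEED = 1


@pytest.fixture(scope="session")
def world():
    """The shipped chagos-like synthetic atoll (session-scoped: building
    the Monte-Carlo mean matrices is the expensive part)."""
    return chagos_like_world(rng_seed=WORLD_SEED)


@pytest.fixture(scope="session")
def recovery_fixture(world):
    """Noise-free 'observed' post-disturbance distributions."""
    return generate_recovery_fixture(world)


@pytest.fixture
def simple_life_table():
    return LifeTableSample(
        growth_form="branching_encrusting",
        sigma=np.array([0.1, 0.4, 0.6, 0.8, 0.9]),
        duration=np.array([1, 2, 3, 4, 1]),
        source_label="unit-test",
    )


@pytest.fixture
def second_life_table():
    return LifeTableSample(
        growth_form="branching_encrusting",
        sigma=np.array([0.05, 0.3, 0.5, 0.7, 0.95]),
        duration=np.array([1, 1, 2, 3, 1]),
        source_label="unit-test-2",
    )
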