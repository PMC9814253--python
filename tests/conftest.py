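import numpy as np
import pytest

from chemloop import (
    EmulatorConfig,
    ObjectiveHierarchy,
    ObjectiveSpec,
    build_emulator,
    default_hierarchy,
    default_space,
)


@pytest.fixture
def space():
    """Campaign-2-style search space: 23 ligands + 3 continuous knobs."""
    return default_space(n_ligands=23)


@pytest.fixture
def hierarchy():
    return default_hierarchy()


@pytest.fixture
def small_space():
    return default_space(n_ligands=4)


@pytest.fixture
def emulator():
    return build_emulator([f"L{i}" for i in range(1, 24)],
                          config=EmulatorConfig(noise_sd=1.5, seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
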