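import numpy as np
import pytest

from cogmap.environment import load_room


@pytest.fixture(scope="session")
def room_and_stimuli():
    return load_room()


@pytest.fixture(scope="session")
def room(room_and_stimuli):
    return room_and_stimuli[0]


@pytest.fixture(scope="session")
def stimuli(room_and_stimuli):
    return room_and_stimuli[1]


@pytest.fixture(scope="session")
def texture_table(stimuli):
    """Deterministic synthetic texture table (cheap stand-in for tests)."""
    n = stimuli.n_conditions
    rng = np.random.default_rng(2024)
    base = rng.uniform(0.2, 1.8, size=(n, n))
    tab = (base + base.T) / 2
    np.fill_diagonal(tab, 0.0)
    # correlate with view distance so orthogonalization plans have bite
    view = stimuli.pairwise("view")
    return 0.5 * tab + 0.4 * view / view.max() * 2.0
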