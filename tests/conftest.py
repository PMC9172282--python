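import numpy as np
import pytest

from votrsa import synthetic as syn


@pytest.fixture(scope="session")
def tiny_anatomy():
    """Minimal phantom for fast searchlight/cluster tests (~1.4k brain voxels)."""
    return syn.make_phantom_anatomy(grid=(14, 30, 10), box=(3, 3, 3), gap=4)


@pytest.fixture(scope="session")
def roster():
    return syn.generate_stimulus_set(11)


@pytest.fixture(scope="session")
def stimuli(roster):
    return roster[0]


@pytest.fixture(scope="session")
def embeddings(roster):
    return roster[1]


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
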