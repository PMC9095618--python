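import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from mcfholo import desk_profile


@pytest.fixture(scope="session")
def profile():
    return desk_profile()


@pytest.fixture(scope="session")
def core_map(profile):
    """Desk-scale 128-core training map."""
    return profile.make_core_map(seed=1)


@pytest.fixture(scope="session")
def core_map_200(profile):
    """Desk-scale 200-core comparison map."""
    return profile.make_core_map(200, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def glyph_targets(profile):
    """A small batch of preprocessed glyph targets on the 64x64 grid."""
    from mcfholo.data import DatasetSpec, generate_targets, preprocess_target

    spec = DatasetSpec(kind="glyphs", count=12, seed=7)
    return [preprocess_target(t, profile.work_size, profile.shape)
            for t in generate_targets(spec)]
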