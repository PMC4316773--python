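import numpy as np
import pytest

import scenespace as sc


@pytest.fixture(scope="session")
def small_stimuli():
    """5 categories x 4 exemplars of 64 px procedural scenes."""
    return sc.gen_scene_images(5, 4, 64, seed=1)


@pytest.fixture(scope="session")
def ortho_spaces():
    """Three orthogonal 20-scene model spaces (190 pairs)."""
    return sc.orthogonal_scene_spaces(20, 3, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
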