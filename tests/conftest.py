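import numpy as np
import pytest

from serdskit import pipeline, scenes
from serdskit.ccd import small_layout


@pytest.fixture(scope="session")
def beads_preset():
    return scenes.beads_scene(grid_shape=(5, 5), n_cycles=3, t_exp=0.1)


@pytest.fixture(scope="session")
def beads_layout(beads_preset):
    return pipeline.layout_for_preset(beads_preset, n_cols=256)


@pytest.fixture(scope="session")
def beads_frame_noise_free(beads_preset, beads_layout):
    """Expected-count (noise-free, no readout) rendering of the beads preset."""
    return pipeline.simulate_preset(
        beads_preset, layout=beads_layout, seed=0, noise=False, readout=False
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
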