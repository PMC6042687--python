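import numpy as np
import pytest
from hypothesis import settings

from ctquant import ChannelSpec, SimulationParams

settings.register_profile("ci", database=None, deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def fast_params():
    """A small, quick-to-render cell for unit tests (not the study conditions)."""
    return SimulationParams(
        nucleus_radii=(1.6, 2.2, 2.2),
        voxel_spacing=(0.25, 0.1, 0.1),
        grid_shape=(32, 64, 64),
        channels=[
            ChannelSpec("A", beads_per_chain=40, step_length=0.5),
            ChannelSpec("B", beads_per_chain=40, step_length=0.5),
        ],
        anchor_min_separation=1.5,
        unpaired_homolog_separation=2.0,
        seed=0,
    )


@pytest.fixture
def default_params():
    return SimulationParams()
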