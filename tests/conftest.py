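import numpy as np
import pytest

from flow4d import GridSpec, PhantomSubject, gen_ventricle_phantom


@pytest.fixture
def small_grid() -> GridSpec:
    """Cubic 16-voxel grid, 2.5 mm spacing, 4 frames."""
    return GridSpec((16, 16, 16), (2.5, 2.5, 2.5), n_frames=4, rr_interval=1.0)


@pytest.fixture
def phantom_grid() -> GridSpec:
    """Grid large enough for a 100 mL beating chamber."""
    return GridSpec((40, 40, 40), (2.5, 2.5, 2.5), n_frames=10)


@pytest.fixture
def default_subject() -> PhantomSubject:
    return PhantomSubject(edv=100.0, esv=60.0, hr=80.0, weight=55.0, flow_scale=1.0)


@pytest.fixture
def beating_phantom(default_subject, phantom_grid):
    """(field, mask, volume_series) for the default subject."""
    return gen_ventricle_phantom(default_subject, phantom_grid)
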