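import numpy as np
import pytest

from otodrill import default_materials, make_sphere_phantom, make_wall_phantom


@pytest.fixture()
def materials():
    return default_materials()


@pytest.fixture()
def sphere8():
    """Solid 8 mm ball at 0.5 mm spacing, with its analytic ground truth."""
    return make_sphere_phantom(radius_mm=8.0, spacing=0.5)


@pytest.fixture()
def wall2():
    """2-voxel-thick flat slab (thin-wall haptics fixture)."""
    return make_wall_phantom(2, nx=24, ny=24, nz=24, spacing=0.5)


@pytest.fixture()
def channel_wall():
    """Thick slab with a 3-voxel-wide straight channel through it."""
    return make_wall_phantom(12, nx=24, ny=24, nz=24, spacing=0.5, channel_width=3)


def random_free_start(volume, rng, margin=2.0):
    """A free-space world point near the volume for trajectory scripting."""
    extent = (np.asarray(volume.dims) - 1) * volume.spacing
    hi = volume.origin + extent
    return np.array([hi[0] / 2.0, hi[1] / 2.0, hi[2] + margin])
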