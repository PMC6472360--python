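import numpy as np
import pytest

from vascatlas import BinaryMask, VolumeImage, make_grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def digital_cylinder(shape, center_xy, radius_vox, axis=2):
    """Binary cylinder along an axis; voxel centers within radius (voxels)."""
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    plane = [i for i in range(3) if i != axis]
    d2 = ((grids[plane[0]] - center_xy[0]) ** 2
          + (grids[plane[1]] - center_xy[1]) ** 2)
    return d2 <= radius_vox ** 2


@pytest.fixture
def cylinder_mask():
    """Radius-3-voxel digital cylinder along z, 1 mm isotropic."""
    m = digital_cylinder((24, 24, 24), (12, 12), 3.0)
    return BinaryMask(m, np.eye(4))


@pytest.fixture
def small_grid():
    return make_grid((16, 16, 16), (1.0, 1.0, 1.0))
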