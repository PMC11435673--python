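import numpy as np
import pytest

from hypofrac import PhantomSpec, Role, RoiMask, Units, VolumeImage, generate_phantom


@pytest.fixture
def iso_grid():
    """A small isotropic 1 mm grid helper: (spacing, affine)."""
    return (1.0, 1.0, 1.0), np.eye(4)


@pytest.fixture
def sphere_mask():
    """Solid digital sphere, radius 10 mm on a 1 mm grid (24^3)."""
    n = 24
    c = (n - 1) / 2.0
    ii, jj, kk = np.meshgrid(*([np.arange(n)] * 3), indexing="ij")
    data = (ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2 <= 10.0 ** 2
    return RoiMask(data=data, role=Role.TUMOR, spacing=(1.0, 1.0, 1.0), affine=np.eye(4))


@pytest.fixture(scope="session")
def small_phantom():
    """One default phantom case (bladder included), generated once."""
    spec = PhantomSpec(seed=7)
    return generate_phantom(spec)


def brute_force_erode(mask: np.ndarray, spacing, radius: float) -> np.ndarray:
    """Exhaustive O(n^2) distance-to-complement erosion oracle.

    Keeps voxels whose minimum Euclidean distance (voxel centres, mm) to
    any background voxel is >= radius. Chunked to bound memory.
    """
    sp = np.asarray(spacing, dtype=float)
    fg = np.argwhere(mask) * sp
    bg = np.argwhere(~mask) * sp
    if bg.size == 0:
        return mask.copy()
    keep = np.zeros(len(fg), dtype=bool)
    for i in range(0, len(fg), 512):
        chunk = fg[i:i + 512]
        d2 = ((chunk[:, None, :] - bg[None, :, :]) ** 2).sum(axis=2)
        keep[i:i + 512] = np.sqrt(d2.min(axis=1)) >= radius
    out = np.zeros_like(mask)
    idx = np.argwhere(mask)[keep]
    out[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return out
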