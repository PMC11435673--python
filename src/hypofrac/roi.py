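"""ROI morphology (mm-exact contraction) and ROI-wise SUV statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import EmptyMaskError, GridMismatchError, Role, RoiMask, VolumeImage


@dataclass
class ReferenceStats:
    """SUV statistics for one ROI.

    ``suv_sd`` is the sample standard deviation (n-1 denominator); a
    single-voxel ROI gets sd 0. ``role`` records which ROI the statistics
    came from so threshold rules can check provenance.
    """

    suv_mean: float
    suv_sd: float
    suv_max: float
    n_voxels: int
    volume_ml: float
    role: Role | None = None

    def __post_init__(self) -> None:
        if self.suv_sd < 0:
            raise ValueError("suv_sd must be >= 0")
        if self.suv_max < self.suv_mean - 1e-9:
            raise ValueError("suv_max must be >= suv_mean")


def erode_mask(m: RoiMask, radius_mm: float) -> RoiMask:
    """Contract a mask by a physical radius in mm.

    Keeps exactly the voxels whose Euclidean distance (anisotropy-aware,
    computed on voxel centres) to the nearest voxel outside the mask is
    >= ``radius_mm``. This gives exact millimetre semantics on anisotropic
    grids, unlike structuring-element erosion.
    """
    if radius_mm < 0:
        raise ValueError(f"radius must be >= 0, got {radius_mm}")
    if radius_mm == 0:
        return RoiMask(data=m.data.copy(), role=m.role, spacing=m.spacing,
                       affine=m.affine.copy())
    dist = ndimage.distance_transform_edt(m.data, sampling=m.spacing)
    out = dist >= radius_mm
    if not out.any():
        raise EmptyMaskError(
            f"mask {m.role.value} empty after contraction by {radius_mm} mm"
        )
    return RoiMask(data=out, role=m.role, spacing=m.spacing, affine=m.affine.copy())


def roi_statistics(v: VolumeImage, m: RoiMask) -> ReferenceStats:
    """Mean, sample SD, max, voxel count and volume (mL) over a mask."""
    if not v.same_grid(m):
        raise GridMismatchError(
            f"image grid {v.data.shape}/{v.spacing} does not match "
            f"mask {m.role.value} grid {m.data.shape}/{m.spacing}"
        )
    vals = np.asarray(v.data[m.data], dtype=float)
    if vals.size == 0:
        raise EmptyMaskError(f"mask {m.role.value} is empty")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return ReferenceStats(
        suv_mean=float(vals.mean()),
        suv_sd=sd,
        suv_max=float(vals.max()),
        n_voxels=int(vals.size),
        volume_ml=vals.size * m.voxel_volume_mm3 / 1000.0,
        role=m.role,
    )
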