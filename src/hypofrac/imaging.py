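"""Volume/mask data model, NIfTI I/O, SUV conversion and mask propagation.

Images and masks live on a regular 3D grid described by a voxel->world
affine (mm). All physical arguments throughout the package (radii, FWHM,
offsets) are in millimetres so that nothing depends on the grid spacing.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger("hypofrac")

F18_HALF_LIFE_MIN = 109.77


class Units(enum.Enum):
    """Physical units of the voxel values of a :class:`VolumeImage`."""

    BQ_PER_ML = "Bq/mL"
    SUV = "SUV"


class Role(enum.Enum):
    """Anatomical role of an ROI mask."""

    TUMOR = "tumor"
    BP = "bp"          # blood pool, iliac artery
    LV = "lv"          # blood pool, left ventricle
    GMC = "gmc"        # gluteus maximus muscle (contracted)
    BLADDER = "bladder"


class GridMismatchError(ValueError):
    """Image and mask do not share a voxel grid."""


class EmptyMaskError(ValueError):
    """An operation produced or received a mask with no voxels."""


def _check_grid(spacing, data) -> None:
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError(f"spacing must be 3 positive mm values, got {spacing}")
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D")
    if any(s < 1 for s in data.shape):
        raise ValueError(f"each axis needs at least 1 voxel, got shape {data.shape}")


@dataclass
class VolumeImage:
    """A 3D scalar image with voxel spacing, world affine and units.

    Parameters
    ----------
    data
        3D array of voxel values (Bq/mL or SUV).
    spacing
        Voxel size per axis in mm; all components strictly positive.
    affine
        4x4 voxel-index -> world-mm transform (NIfTI convention).
    units
        :class:`Units` member describing what ``data`` holds.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    units: Units

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        _check_grid(self.spacing, self.data)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not isinstance(self.units, Units):
            raise ValueError(f"units must be a Units member, got {self.units!r}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "VolumeImage | RoiMask") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.affine, other.affine, atol=1e-6)
        )


@dataclass
class RoiMask:
    """A binary region-of-interest mask sharing a grid with an image."""

    data: np.ndarray
    role: Role
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        _check_grid(self.spacing, self.data)
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask for role {self.role} has non-binary values {vals[:5]}")
        self.data = self.data.astype(bool)
        if not isinstance(self.role, Role):
            raise ValueError(f"role must be a Role member, got {self.role!r}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3 / 1000.0

    def same_grid(self, other: "VolumeImage | RoiMask") -> bool:
        return VolumeImage.same_grid(self, other)  # type: ignore[arg-type]


@dataclass
class ScanMeta:
    """Injection and patient metadata needed for SUV conversion.

    ``half_life_min`` defaults to 18F (109.77 min); override for other
    radionuclides.
    """

    injected_activity_mbq: float
    injection_to_scan_min: float
    body_weight_kg: float
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        for name in ("injected_activity_mbq", "injection_to_scan_min",
                     "body_weight_kg", "half_life_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScanMeta":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            injected_activity_mbq=d["injected_activity_mbq"],
            injection_to_scan_min=d["injection_to_scan_min"],
            body_weight_kg=d["body_weight_kg"],
            half_life_min=d.get("half_life_min", F18_HALF_LIFE_MIN),
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "injected_activity_mbq": self.injected_activity_mbq,
                    "injection_to_scan_min": self.injection_to_scan_min,
                    "body_weight_kg": self.body_weight_kg,
                    "half_life_min": self.half_life_min,
                },
                fh,
                indent=2,
            )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def load_volume(path: str | Path, units: Units = Units.SUV) -> VolumeImage:
    """Load a 3D NIfTI-1 volume.

    The caller declares the units the file holds (NIfTI does not carry
    them). Non-finite voxels are rejected explicitly rather than silently
    propagated through downstream statistics.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    elif data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D with shape {data.shape}")
    n_bad = int(np.count_nonzero(~np.isfinite(data)))
    if n_bad:
        raise ValueError(f"{path.name}: {n_bad} non-finite voxels")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(data=data, spacing=spacing, affine=np.asarray(img.affine), units=units)


def save_volume(v: VolumeImage, path: str | Path) -> None:
    """Write a volume as float32 NIfTI-1; overwrites an existing file."""
    path = Path(path)
    if path.exists():
        logger.info("overwriting %s", path)
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), v.affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def load_mask(path: str | Path, role: Role) -> RoiMask:
    """Load a binary ROI mask (0/1 NIfTI) and tag it with its role."""
    v = load_volume(path, units=Units.SUV)
    return RoiMask(data=v.data, role=role, spacing=v.spacing, affine=v.affine)


def save_mask(m: RoiMask, path: str | Path) -> None:
    path = Path(path)
    if path.exists():
        logger.info("overwriting %s", path)
    img = nib.Nifti1Image(m.data.astype(np.uint8), m.affine)
    img.header.set_zooms(m.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# SUV conversion
# ---------------------------------------------------------------------------

def activity_to_suv(v: VolumeImage, meta: ScanMeta) -> VolumeImage:
    """Convert an activity-concentration image (Bq/mL) to body-weight SUV.

    SUV(x) = C(x) [Bq/mL] * W [g] / (D_injected [Bq] * 2^(-t / T_half)),
    i.e. the injected dose is decay-corrected to the scan time before
    normalisation. Linear in C.
    """
    if v.units is not Units.BQ_PER_ML:
        raise ValueError(f"expected Bq/mL input, got {v.units}")
    decay = 2.0 ** (-meta.injection_to_scan_min / meta.half_life_min)
    dose_bq = meta.injected_activity_mbq * 1e6
    weight_g = meta.body_weight_kg * 1e3
    scale = weight_g / (dose_bq * decay)
    return replace(v, data=v.data * scale, units=Units.SUV)


# ---------------------------------------------------------------------------
# Mask propagation between grids
# ---------------------------------------------------------------------------

def propagate_mask(m: RoiMask, target: VolumeImage) -> RoiMask:
    """Resample a mask onto the grid of ``target`` (nearest neighbour).

    Each target voxel centre is mapped through the two affines into the
    source index space and sampled with nearest-neighbour interpolation,
    which preserves binarity — the semantics of propagating a contour from
    MR onto PET. An empty result (no world overlap) is an error, never a
    silent success.
    """
    if m.same_grid(target):
        return RoiMask(data=m.data.copy(), role=m.role,
                       spacing=target.spacing, affine=target.affine.copy())
    try:
        src_inv = np.linalg.inv(m.affine)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular source affine") from exc
    # target index -> world -> source index
    M = src_inv @ target.affine
    shape = target.data.shape
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]),
        indexing="ij", sparse=False,
    )
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)], axis=0)
    src = M @ idx
    src = np.rint(src[:3]).astype(np.int64)
    inb = (
        (src[0] >= 0) & (src[0] < m.data.shape[0])
        & (src[1] >= 0) & (src[1] < m.data.shape[1])
        & (src[2] >= 0) & (src[2] < m.data.shape[2])
    )
    out = np.zeros(ii.size, dtype=bool)
    out[inb] = m.data[src[0][inb], src[1][inb], src[2][inb]]
    out = out.reshape(shape)
    if not out.any():
        raise EmptyMaskError(
            f"mask {m.role.value} is empty after propagation: no overlap with the target field of view"
        )
    return RoiMask(data=out, role=m.role, spacing=target.spacing, affine=target.affine.copy())
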