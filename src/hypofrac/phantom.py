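"""Digital pelvic phantom with known ground truth.

Emulates the imaging conditions of a FAZA PET hypoxia study of the pelvis:
a rectal tumor (ellipsoid) containing a contiguous hypoxic cap sized to a
known true hypoxic fraction, reference regions (left-ventricle sphere,
narrow iliac-artery cylinder, bilateral gluteus maximus muscle), an
optional hot bladder abutting the tumor to produce spill-in, an isotropic
Gaussian point-spread blur, and additive Gaussian noise. Masks are
pre-blur ground truth; the blurred, noisy PET is what the quantification
pipeline sees.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .imaging import Role, RoiMask, Units, VolumeImage, save_mask, save_volume

logger = logging.getLogger("hypofrac")

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PhantomSpec:
    """Parameters of one synthetic case.

    Defaults emulate the study acquisition: 2.8 mm PET grid, 4.5 mm FWHM
    reconstruction blur, ~20 mL tumor, oxic tumor tissue at SUV 1.0,
    hypoxic at 2.0, blood at 1.2, muscle at 0.9, bladder at 10. The
    hypoxic cap occupies ``true_hf`` percent of tumor voxels.
    ``bladder_offset_mm`` is the gap between bladder and tumor surfaces
    (0 = abutting); ``include_bladder`` False removes the bladder
    entirely. Soft-tissue background is 0.8 (slightly below muscle).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (2.8, 2.8, 2.8)
    tumor_center_mm: tuple[float, float, float] = (134.0, 170.0, 67.0)
    tumor_semi_axes_mm: tuple[float, float, float] = (20.0, 17.0, 14.0)
    true_hf: float = 30.0
    oxic_mean: float = 1.0
    oxic_sd: float = 0.15
    hypoxic_mean: float = 2.0
    hypoxic_sd: float = 0.2
    blood_level: float = 1.2
    muscle_level: float = 0.9
    bladder_level: float = 10.0
    bladder_offset_mm: float = 0.0
    bladder_radius_mm: float = 25.0
    include_bladder: bool = True
    background_level: float = 0.8
    psf_fwhm_mm: float = 4.5
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.true_hf <= 100:
            raise ValueError(f"true_hf must be in [0, 100], got {self.true_hf}")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")
        for name in ("oxic_mean", "hypoxic_mean", "blood_level", "muscle_level",
                     "bladder_level", "background_level"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def _world_grid(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sp = spec.spacing
    ax = [np.arange(n) * s for n, s in zip(spec.grid_shape, sp)]
    return np.meshgrid(*ax, indexing="ij", sparse=True)


def _ellipsoid(xx, yy, zz, center, semi) -> np.ndarray:
    return (
        ((xx - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((zz - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _truncated_normal(rng, mean, sd, n, lower=-np.inf, upper=np.inf) -> np.ndarray:
    if sd == 0 or n == 0:
        return np.full(n, mean)
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeImage, dict[Role, RoiMask], dict]:
    """Build one synthetic case.

    Returns the PET volume (SUV), the pre-blur ground-truth masks
    (TUMOR/BP/LV/GMC and, when present, BLADDER) and a truth dict with the
    realized hypoxic fraction and per-region assigned means. Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    xx, yy, zz = _world_grid(spec)
    affine = np.diag([*spec.spacing, 1.0])

    tumor = _ellipsoid(xx, yy, zz, spec.tumor_center_mm, spec.tumor_semi_axes_mm)
    n_tumor = int(tumor.sum())
    if n_tumor == 0:
        raise ValueError("tumor ellipsoid contains no voxels on this grid")

    # hypoxic cap: the posterior (largest-y) slice of the tumor, sized to
    # exactly round(true_hf% of tumor voxels); plane cut => contiguous
    n_hyp = int(round(spec.true_hf / 100.0 * n_tumor))
    hypoxic = np.zeros_like(tumor)
    if n_hyp > 0:
        ti, tj, tk = np.nonzero(tumor)
        y_mm = tj * spec.spacing[1]
        order = np.lexsort((tk, ti, -y_mm))[:n_hyp]
        hypoxic[ti[order], tj[order], tk[order]] = True

    cx, cy, cz = spec.tumor_center_mm
    lv = _ellipsoid(xx, yy, zz, (60.0, 60.0, 100.0), (20.0, 20.0, 20.0))
    bp = (((xx - 200.0) ** 2 + (yy - 60.0) ** 2) <= 4.0 ** 2) & (zz >= 20.0) & (zz <= 115.0)
    gmc = _ellipsoid(xx, yy, zz, (80.0, 230.0, cz), (25.0, 20.0, 30.0)) | _ellipsoid(
        xx, yy, zz, (188.0, 230.0, cz), (25.0, 20.0, 30.0)
    )
    masks_bool = {Role.TUMOR: tumor, Role.LV: lv, Role.BP: bp, Role.GMC: gmc}

    if spec.include_bladder:
        by = cy - spec.tumor_semi_axes_mm[1] - spec.bladder_radius_mm - spec.bladder_offset_mm
        bladder = _ellipsoid(xx, yy, zz, (cx, by, cz),
                             (spec.bladder_radius_mm,) * 3) & ~tumor
        masks_bool[Role.BLADDER] = bladder

    vol = np.full(spec.grid_shape, spec.background_level, dtype=float)
    vol[gmc] = spec.muscle_level
    vol[lv] = spec.blood_level
    vol[bp] = spec.blood_level
    if spec.include_bladder:
        vol[masks_bool[Role.BLADDER]] = spec.bladder_level
    # class-consistent draws: each voxel's true class stays on its side of
    # the oxic/hypoxic midpoint (truncation >= 2.5 sd out, so the Gaussians
    # are essentially unaltered), which makes true_hf exactly recoverable
    # when blur and noise are off
    midpoint = 0.5 * (spec.oxic_mean + spec.hypoxic_mean)
    oxic = tumor & ~hypoxic
    vol[oxic] = _truncated_normal(
        rng, spec.oxic_mean, spec.oxic_sd, int(oxic.sum()), upper=midpoint)
    vol[hypoxic] = _truncated_normal(
        rng, spec.hypoxic_mean, spec.hypoxic_sd, n_hyp, lower=midpoint)

    if spec.psf_fwhm_mm > 0:
        sigma_vox = [spec.psf_fwhm_mm * FWHM_TO_SIGMA / s for s in spec.spacing]
        vol = ndimage.gaussian_filter(vol, sigma=sigma_vox)
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, vol.shape)

    pet = VolumeImage(data=vol, spacing=spec.spacing, affine=affine, units=Units.SUV)
    masks = {
        role: RoiMask(data=arr, role=role, spacing=spec.spacing, affine=affine.copy())
        for role, arr in masks_bool.items()
    }
    truth = {
        "true_hf": 100.0 * n_hyp / n_tumor,
        "requested_hf": spec.true_hf,
        "n_tumor": n_tumor,
        "n_hypoxic": n_hyp,
        "region_means": {
            "oxic": spec.oxic_mean,
            "hypoxic": spec.hypoxic_mean,
            "blood": spec.blood_level,
            "muscle": spec.muscle_level,
            "bladder": spec.bladder_level if spec.include_bladder else None,
            "background": spec.background_level,
        },
        "class_midpoint": 0.5 * (spec.oxic_mean + spec.hypoxic_mean),
        "seed": spec.seed,
    }
    return pet, masks, truth


@dataclass
class PhantomCase:
    """One generated case, optionally paired across timepoints."""

    patient_id: str
    timepoint: str
    spec: PhantomSpec
    pet: VolumeImage
    masks: dict[Role, RoiMask]
    truth: dict


def generate_cohort(
    n_patients: int,
    hf_range: tuple[float, float] = (0.0, 73.0),
    paired: bool = False,
    seed: int = 0,
    out_dir: str | Path | None = None,
    base_spec: PhantomSpec | None = None,
    followup_volume_scale: float = 0.3,
) -> list[PhantomCase]:
    """Generate a cohort of phantom cases with uniform-random true HF.

    Paired patients get a follow-up scan with tumor volume scaled by
    ``followup_volume_scale`` (default 0.3, matching the ~70% shrinkage
    seen after chemoradiotherapy) and an independently drawn HF. With
    ``out_dir`` set, each case is written as NIfTI volumes + a JSON truth
    sidecar, plus a cohort manifest CSV.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    lo, hi = hf_range
    if not (0 <= lo <= hi <= 100):
        raise ValueError(f"invalid hf_range {hf_range}")
    base = base_spec if base_spec is not None else PhantomSpec()
    ss = np.random.SeedSequence(seed)
    draw_rng = np.random.default_rng(ss.spawn(1)[0])
    case_seeds = iter(np.random.default_rng(seed).integers(0, 2**31 - 1, size=4 * n_patients))

    cases: list[PhantomCase] = []
    axis_scale = followup_volume_scale ** (1.0 / 3.0)
    for i in range(n_patients):
        pid = f"S{i + 1:02d}"
        timepoints = [("baseline", 1.0)] + ([("followup", axis_scale)] if paired else [])
        for tp, scale in timepoints:
            hf = float(draw_rng.uniform(lo, hi))
            spec = replace(
                base,
                true_hf=hf,
                tumor_semi_axes_mm=tuple(a * scale for a in base.tumor_semi_axes_mm),
                seed=int(next(case_seeds)),
            )
            pet, masks, truth = generate_phantom(spec)
            cases.append(PhantomCase(pid, tp, spec, pet, masks, truth))

    if out_dir is not None:
        _write_cohort(cases, Path(out_dir))
    return cases


def _write_cohort(cases: list[PhantomCase], out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for case in cases:
        cdir = out_dir / f"{case.patient_id}_{case.timepoint}"
        cdir.mkdir(exist_ok=True)
        save_volume(case.pet, cdir / "pet.nii.gz")
        for role, mask in case.masks.items():
            save_mask(mask, cdir / f"{role.value}.nii.gz")
        with open(cdir / "truth.json", "w") as fh:
            json.dump(case.truth, fh, indent=2)
        manifest.append({
            "patient_id": case.patient_id,
            "timepoint": case.timepoint,
            "case_dir": cdir.name,
            "true_hf": case.truth["true_hf"],
            "seed": case.spec.seed,
        })
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(manifest[0]))
        writer.writeheader()
        writer.writerows(manifest)
    logger.info("wrote %d cases to %s", len(cases), out_dir)
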