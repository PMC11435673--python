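"""Voxel classification into oxic/hypoxic and the derived summary metrics.

A tumor voxel is hypoxic when its SUV exceeds a threshold derived from a
normally oxygenated reference tissue: a multiple (x1.0 or x1.2) of the
blood-pool SUVmean (iliac artery or left ventricle), or muscle
SUVmean + 3SD (contracted gluteus maximus). The hypoxic fraction (HF) is
the percentage of tumor voxels above threshold; TRR is tumor SUVmax over
reference SUVmean.
"""

from __future__ import annotations

import decimal
import enum
import logging
from dataclasses import dataclass

import numpy as np

from .imaging import Role
from .roi import ReferenceStats

logger = logging.getLogger("hypofrac")


class Rule(enum.Enum):
    SCALE = "scale"                  # factor * SUVmean
    MEAN_PLUS_SD = "mean_plus_sd"    # SUVmean + n_sd * SD


@dataclass(frozen=True)
class ThresholdScheme:
    """One reference/threshold rule, e.g. x1.2 of LV SUVmean."""

    reference_role: Role
    rule: Rule
    factor: float = 1.0   # used by SCALE
    n_sd: float = 3.0     # used by MEAN_PLUS_SD

    def __post_init__(self) -> None:
        standard = (
            (self.rule is Rule.SCALE and self.reference_role in (Role.BP, Role.LV))
            or (self.rule is Rule.MEAN_PLUS_SD and self.reference_role is Role.GMC)
        )
        if not standard:
            logger.warning("non-standard scheme %s; allowed but not a study scheme", self)

    @property
    def label(self) -> str:
        if self.rule is Rule.SCALE:
            return f"{self.reference_role.value.upper()}_x{self.factor:g}"
        return f"{self.reference_role.value.upper()}_+{self.n_sd:g}SD"


#: The five reference/threshold schemes evaluated in the study.
STUDY_SCHEMES: tuple[ThresholdScheme, ...] = (
    ThresholdScheme(Role.GMC, Rule.MEAN_PLUS_SD, n_sd=3.0),
    ThresholdScheme(Role.BP, Rule.SCALE, factor=1.0),
    ThresholdScheme(Role.LV, Rule.SCALE, factor=1.0),
    ThresholdScheme(Role.BP, Rule.SCALE, factor=1.2),
    ThresholdScheme(Role.LV, Rule.SCALE, factor=1.2),
)


@dataclass
class HypoxiaResult:
    """Per-case outcome under one threshold scheme."""

    scheme: ThresholdScheme
    threshold: float
    n_hypoxic: int
    n_total: int
    hf_percent: float
    trr: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_hypoxic <= self.n_total:
            raise ValueError("need 0 <= n_hypoxic <= n_total")
        if abs(self.hf_percent - 100.0 * self.n_hypoxic / self.n_total) > 1e-9:
            raise ValueError("hf_percent inconsistent with counts")


def threshold_from_reference(stats: ReferenceStats, scheme: ThresholdScheme) -> float:
    """SUV threshold for a scheme: factor*mean (SCALE) or mean + n_sd*SD."""
    if stats.role is not None and stats.role is not scheme.reference_role:
        raise ValueError(
            f"scheme expects {scheme.reference_role.value} statistics, "
            f"got {stats.role.value}"
        )
    if scheme.rule is Rule.SCALE:
        return scheme.factor * stats.suv_mean
    return stats.suv_mean + scheme.n_sd * stats.suv_sd


def classify_voxels(tumor_values, threshold: float, strict: bool = True) -> tuple[int, int]:
    """Count hypoxic voxels (value > threshold; ``strict=False`` uses >=)."""
    x = np.asarray(tumor_values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("no tumor voxels to classify")
    n_hyp = int((x > threshold).sum()) if strict else int((x >= threshold).sum())
    return n_hyp, int(x.size)


def hypoxic_fraction(n_hypoxic: int, n_total: int) -> float:
    """HF in percent: 100 * hypoxic voxels / total tumor voxels."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    return 100.0 * n_hypoxic / n_total


def trr(tumor_suv_max: float, ref_suv_mean: float) -> float:
    """Tumor SUVmax to reference SUVmean ratio."""
    if ref_suv_mean <= 0:
        raise ValueError("reference SUVmean must be > 0")
    return tumor_suv_max / ref_suv_mean


def relative_change(pre_value: float, post_value: float) -> float:
    """Signed percent change 100*(post - pre)/pre."""
    if pre_value == 0:
        raise ValueError("pre_value must be nonzero")
    return 100.0 * (post_value - pre_value) / pre_value


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed clinical tables)."""
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))
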