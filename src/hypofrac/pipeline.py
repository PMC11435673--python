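"""Configuration-driven orchestration: per-case quantification and reports.

``run_case`` executes the full measurement chain on one case: SUV
conversion (when needed), mask propagation onto the PET grid, muscle
contraction, reference statistics, bladder spill correction of the tumor
voxels, and per-scheme threshold/HF/TRR results.
``reproduce_cohort_report`` recomputes the printed cohort summaries from
the packaged transcription and flags each against the printed value.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    SCHEME_KEYS,
    CohortTable,
    change_table,
    correlation_table,
    load_study_cohort,
    load_printed_summaries,
    mean_volume_change,
    summarize_hf,
)
from .hypoxia import (
    STUDY_SCHEMES,
    HypoxiaResult,
    ThresholdScheme,
    classify_voxels,
    hypoxic_fraction,
    round_half_away,
    threshold_from_reference,
    trr,
)
from .imaging import (
    Role,
    RoiMask,
    ScanMeta,
    Units,
    VolumeImage,
    activity_to_suv,
    load_mask,
    load_volume,
    propagate_mask,
)
from .roi import ReferenceStats, erode_mask, roi_statistics
from .spill import SpillModel, correct_bladder_spill

logger = logging.getLogger("hypofrac")


@dataclass
class RunConfig:
    """Pipeline settings.

    ``hf_denominator`` selects whether the HF denominator is the
    spill-corrected (retained) voxel set — removed voxels are declared
    non-tumor signal and count in neither numerator nor denominator — or
    the original tumor voxel count ("original", for sensitivity analysis).
    """

    schemes: tuple[ThresholdScheme, ...] = STUDY_SCHEMES
    spill_enabled: bool = True
    spill_k: float = 3.0
    spill_max_iter: int = 10
    gmc_erosion_mm: float = 4.0
    strict_threshold: bool = True
    hf_denominator: str = "retained"  # or "original"
    round_decimals: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.schemes:
            raise ValueError("at least one threshold scheme is required")
        if self.hf_denominator not in ("retained", "original"):
            raise ValueError("hf_denominator must be 'retained' or 'original'")

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d["schemes"] = [s.label for s in self.schemes]
        return hashlib.sha1(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class CaseData:
    """One case's inputs: PET volume plus co-registered role masks."""

    pet: VolumeImage
    masks: dict[Role, RoiMask]
    patient_id: str = "case"
    timepoint: str = "baseline"
    meta: ScanMeta | None = None

    @classmethod
    def from_dir(cls, case_dir: str | Path, units: Units = Units.SUV) -> "CaseData":
        """Load ``pet.nii.gz`` and any ``<role>.nii.gz`` masks from a directory.

        A ``meta.json`` sidecar (injected activity, timing, weight), when
        present, enables Bq/mL -> SUV conversion.
        """
        case_dir = Path(case_dir)
        pet = load_volume(case_dir / "pet.nii.gz", units=units)
        masks = {}
        for role in Role:
            p = case_dir / f"{role.value}.nii.gz"
            if p.exists():
                masks[role] = load_mask(p, role)
        meta_path = case_dir / "meta.json"
        meta = ScanMeta.from_json(meta_path) if meta_path.exists() else None
        name = case_dir.name
        pid, _, tp = name.rpartition("_")
        return cls(pet=pet, masks=masks, patient_id=pid or name,
                   timepoint=tp if tp in ("baseline", "followup") else "baseline",
                   meta=meta)


@dataclass
class CaseResult:
    """Everything measured on one case."""

    patient_id: str
    timepoint: str
    results: list[HypoxiaResult]
    spill_model: SpillModel
    tumor_stats_raw: ReferenceStats
    tumor_stats_corrected: ReferenceStats
    reference_stats: dict[Role, ReferenceStats]

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {
                "patient_id": self.patient_id,
                "timepoint": self.timepoint,
                "scheme": r.scheme.label,
                "threshold": r.threshold,
                "n_hypoxic": r.n_hypoxic,
                "n_total": r.n_total,
                "hf_percent": r.hf_percent,
                "trr": r.trr,
                "tumor_suv_max_raw": self.tumor_stats_raw.suv_max,
                "tumor_suv_max_corrected": self.tumor_stats_corrected.suv_max,
                "spill_removed": self.spill_model.n_removed,
            }
            if decimals is not None:
                for col in ("threshold", "hf_percent", "trr"):
                    row[col] = round_half_away(row[col], decimals)
            rows.append(row)
        return pd.DataFrame(rows)


def run_case(config: RunConfig, case: CaseData) -> CaseResult:
    """Quantify one case under every requested scheme.

    Missing reference masks skip their schemes with a warning rather than
    aborting. The tumor mask is mandatory.
    """
    pet = case.pet
    if pet.units is Units.BQ_PER_ML:
        if case.meta is None:
            raise ValueError("PET is in Bq/mL but no scan metadata was provided")
        pet = activity_to_suv(pet, case.meta)
        logger.info("%s/%s: converted Bq/mL to SUV", case.patient_id, case.timepoint)

    if Role.TUMOR not in case.masks:
        raise ValueError(f"{case.patient_id}: tumor mask is required")
    masks: dict[Role, RoiMask] = {}
    for role, m in case.masks.items():
        masks[role] = m if m.same_grid(pet) else propagate_mask(m, pet)

    ref_stats: dict[Role, ReferenceStats] = {}
    for role in (Role.BP, Role.LV, Role.GMC):
        if role not in masks:
            continue
        m = masks[role]
        if role is Role.GMC and config.gmc_erosion_mm > 0:
            m = erode_mask(m, config.gmc_erosion_mm)
        ref_stats[role] = roi_statistics(pet, m)

    tumor_values = np.asarray(pet.data[masks[Role.TUMOR].data], dtype=float)
    stats_raw = roi_statistics(pet, masks[Role.TUMOR])
    if config.spill_enabled:
        retained_idx, spill_model = correct_bladder_spill(
            tumor_values, k=config.spill_k, max_iter=config.spill_max_iter
        )
    else:
        retained_idx = np.arange(tumor_values.size)
        spill_model = SpillModel(mu=float("nan"), sigma=float("nan"),
                                 cut=float("inf"), k=config.spill_k,
                                 n_removed=0, n_retained=tumor_values.size,
                                 iterations=0, applied=False)
    retained = tumor_values[retained_idx]
    sd = float(np.std(retained, ddof=1)) if retained.size > 1 else 0.0
    stats_corr = ReferenceStats(
        suv_mean=float(retained.mean()), suv_sd=sd, suv_max=float(retained.max()),
        n_voxels=int(retained.size),
        volume_ml=retained.size * masks[Role.TUMOR].voxel_volume_mm3 / 1000.0,
        role=Role.TUMOR,
    )

    results: list[HypoxiaResult] = []
    for scheme in config.schemes:
        if scheme.reference_role not in ref_stats:
            logger.warning(
                "%s/%s: no %s mask, skipping scheme %s",
                case.patient_id, case.timepoint,
                scheme.reference_role.value, scheme.label,
            )
            continue
        stats = ref_stats[scheme.reference_role]
        thr = threshold_from_reference(stats, scheme)
        n_hyp, n_ret = classify_voxels(retained, thr, strict=config.strict_threshold)
        n_total = tumor_values.size if config.hf_denominator == "original" else n_ret
        results.append(HypoxiaResult(
            scheme=scheme,
            threshold=thr,
            n_hypoxic=n_hyp,
            n_total=n_total,
            hf_percent=hypoxic_fraction(n_hyp, n_total),
            trr=trr(stats_corr.suv_max, stats.suv_mean),
        ))
    return CaseResult(
        patient_id=case.patient_id, timepoint=case.timepoint,
        results=results, spill_model=spill_model,
        tumor_stats_raw=stats_raw, tumor_stats_corrected=stats_corr,
        reference_stats=ref_stats,
    )


def run_cases(config: RunConfig, cases) -> pd.DataFrame:
    """Run every case and concatenate the per-scheme result rows."""
    frames = [run_case(config, c).to_frame() for c in cases]
    return pd.concat(frames, ignore_index=True)


def write_table(df: pd.DataFrame, path: str | Path, config: RunConfig | None = None) -> None:
    """Write a CSV with a provenance header (config hash + version)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# hypofrac {__version__}\n")
        if config is not None:
            fh.write(f"# config_hash {config.hash()}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# Cohort reproduction report
# ---------------------------------------------------------------------------

def reproduce_cohort_report(cohort: CohortTable | None = None) -> dict:
    """Recompute the printed cohort summaries and flag each against print.

    Returns a dict of DataFrames: baseline HF medians/ranges, pooled
    TRR-HF Pearson correlations, per-patient therapy-change metrics, and
    the scalar mean tumor-volume decrease. Correlations known not to be
    recoverable from the printed per-patient tables (the BP pair) carry
    ``asserted=False`` and are shown side by side without a match claim.
    """
    if cohort is None:
        cohort = load_study_cohort()
    printed = load_printed_summaries()

    med_rows = []
    for scheme in SCHEME_KEYS:
        med, lo, hi = summarize_hf(cohort.hf(scheme, "baseline"))
        p = printed["baseline_hf"].get(scheme, {})
        med_r = round_half_away(med, 1)
        med_rows.append({
            "scheme": scheme,
            "median_computed": med_r, "median_printed": p.get("median"),
            "min_computed": lo, "max_computed": hi,
            "min_printed": p.get("min"), "max_printed": p.get("max"),
            "median_match": med_r == p.get("median"),
        })
    medians = pd.DataFrame(med_rows)

    corr = correlation_table(cohort)
    corr["r_printed"] = corr["scheme"].map(printed["trr_hf_pearson_r"])
    corr["asserted"] = corr["scheme"].isin(printed["asserted_correlations"])
    corr["match"] = (corr["r"] - corr["r_printed"]).abs() <= 0.02

    changes = change_table(cohort)
    chg_rows = []
    for ref in ("GMc", "BP", "LV"):
        for _, row in changes.iterrows():
            pid = row["patient_id"]
            computed = round_half_away(row[f"dTRR_{ref}_percent"], 1)
            printed_val = printed["trr_relative_change"].get(ref, {}).get(pid)
            chg_rows.append({
                "reference": ref, "patient_id": pid,
                "dTRR_computed": computed, "dTRR_printed": printed_val,
                "match": printed_val is not None and computed == printed_val,
            })
    trr_changes = pd.DataFrame(chg_rows)

    vol = mean_volume_change(cohort)
    return {
        "baseline_hf_summary": medians,
        "correlations": corr,
        "trr_changes": trr_changes,
        "hf_changes": changes[["patient_id"] + [f"dHF_{s}" for s in SCHEME_KEYS]],
        "mean_volume_decrease_percent": round_half_away(vol, 1),
        "mean_volume_decrease_printed": printed["mean_volume_decrease_percent"],
        "notes": printed.get("notes", {}),
    }


def report_to_text(report: dict) -> str:
    """Plain-text rendering of :func:`reproduce_cohort_report`."""
    out = []
    out.append("Baseline HF medians/ranges (computed vs printed)")
    out.append(report["baseline_hf_summary"].to_string(index=False))
    out.append("")
    out.append("Pooled TRR-HF Pearson correlations (computed vs printed)")
    out.append(report["correlations"].to_string(index=False))
    out.append("")
    out.append("Relative TRR change after therapy (computed vs printed)")
    out.append(report["trr_changes"].to_string(index=False))
    out.append("")
    out.append("HF change after therapy (percentage points)")
    out.append(report["hf_changes"].to_string(index=False))
    out.append("")
    out.append(
        f"Mean tumor-volume decrease: {report['mean_volume_decrease_percent']}% "
        f"(printed {report['mean_volume_decrease_printed']}%)"
    )
    for key, note in report.get("notes", {}).items():
        out.append(f"note[{key}]: {note}")
    return "\n".join(out)
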