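"""Cohort-level statistics: HF summaries, TRR-HF correlation, therapy change.

The packaged fixture transcribes the study cohort (8 baseline + 4 follow-up
rectal-cancer cases): per-case tumor volume, SUVmax, reference SUVmean/SD
for muscle (GMc) and blood pool (iliac BP, left-ventricle LV), and the
hypoxic fractions under the five reference/threshold schemes.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .hypoxia import relative_change

#: scheme keys used in cohort tables, in study presentation order
SCHEME_KEYS = ("GMc+3SD", "BPx1.0", "LVx1.0", "BPx1.2", "LVx1.2")

_HF_COLS = {
    "GMc+3SD": "hf_gmc3sd",
    "BPx1.0": "hf_bp10",
    "LVx1.0": "hf_lv10",
    "BPx1.2": "hf_bp12",
    "LVx1.2": "hf_lv12",
}
_REF_COL = {"GMc+3SD": "gmc_mean", "BPx1.0": "bp_mean", "LVx1.0": "lv_mean",
            "BPx1.2": "bp_mean", "LVx1.2": "lv_mean"}
_REF_OF_SCHEME = {"GMc+3SD": "GMc", "BPx1.0": "BP", "LVx1.0": "LV",
                  "BPx1.2": "BP", "LVx1.2": "LV"}
_REF_MEAN = {"GMc": "gmc_mean", "BP": "bp_mean", "LV": "lv_mean"}


@dataclass
class CohortTable:
    """Per-patient, per-timepoint records backing the cohort statistics.

    ``df`` has one row per (patient_id, timepoint) with volume_ml,
    tumor_suv_max, reference means/SDs and per-scheme HF columns.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.df.duplicated(subset=["patient_id", "timepoint"])
        if dup.any():
            raise ValueError("duplicate (patient_id, timepoint) rows")
        missing = {c for c in _HF_COLS.values() if c not in self.df.columns}
        missing |= {c for c in _REF_MEAN.values() if c not in self.df.columns}
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")

    def baseline(self) -> pd.DataFrame:
        return self.df[self.df.timepoint == "baseline"]

    def followup(self) -> pd.DataFrame:
        return self.df[self.df.timepoint == "followup"]

    def hf(self, scheme: str, timepoint: str | None = None) -> np.ndarray:
        d = self.df if timepoint is None else self.df[self.df.timepoint == timepoint]
        return d[_HF_COLS[scheme]].to_numpy(dtype=float)

    def trr(self, scheme: str, timepoint: str | None = None) -> np.ndarray:
        d = self.df if timepoint is None else self.df[self.df.timepoint == timepoint]
        return (d["tumor_suv_max"] / d[_REF_COL[scheme]]).to_numpy(dtype=float)

    def paired_patients(self) -> list[str]:
        b = set(self.baseline().patient_id)
        f = set(self.followup().patient_id)
        return sorted(b & f, key=lambda p: (len(p), p))


def load_study_cohort() -> CohortTable:
    """Load the packaged transcription of the study cohort tables."""
    with importlib.resources.files("hypofrac.data").joinpath("study_cohort.csv").open() as fh:
        return CohortTable(pd.read_csv(fh))


def load_printed_summaries() -> dict:
    """Printed cohort summary values, for side-by-side comparison reports."""
    with importlib.resources.files("hypofrac.data").joinpath("printed_summaries.json").open() as fh:
        return json.load(fh)


def summarize_hf(values) -> tuple[float, float, float]:
    """(median, min, max) of a set of HF percentages (mid-mean for even n)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("no HF values to summarize")
    return float(np.median(x)), float(x.min()), float(x.max())


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment r with two-sided p (t transform, df = n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate input: zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def change_table(cohort: CohortTable) -> pd.DataFrame:
    """Per-patient therapy-change metrics for patients with both timepoints.

    One row per paired patient: delta-HF (percentage points, post - pre)
    per scheme and relative TRR change (%) per reference tissue. Patients
    missing a timepoint are excluded listwise.
    """
    rows = []
    b = cohort.baseline().set_index("patient_id")
    f = cohort.followup().set_index("patient_id")
    for pid in cohort.paired_patients():
        row: dict = {"patient_id": pid}
        for scheme, col in _HF_COLS.items():
            row[f"dHF_{scheme}"] = float(f.loc[pid, col]) - float(b.loc[pid, col])
        for ref, col in _REF_MEAN.items():
            pre = float(b.loc[pid, "tumor_suv_max"]) / float(b.loc[pid, col])
            post = float(f.loc[pid, "tumor_suv_max"]) / float(f.loc[pid, col])
            row[f"dTRR_{ref}_percent"] = relative_change(pre, post)
        rows.append(row)
    if not rows:
        raise ValueError("no patients with both timepoints")
    return pd.DataFrame(rows)


def mean_volume_change(cohort: CohortTable) -> float:
    """Mean per-patient relative tumor-volume decrease, in percent.

    The mean of per-patient percent changes (not the percent change of the
    mean volume); a decrease is reported as a positive percentage.
    """
    b = cohort.baseline().set_index("patient_id")
    f = cohort.followup().set_index("patient_id")
    pids = cohort.paired_patients()
    if not pids:
        raise ValueError("no patients with both timepoints")
    decreases = [
        -relative_change(float(b.loc[p, "volume_ml"]), float(f.loc[p, "volume_ml"]))
        for p in pids
    ]
    return float(np.mean(decreases))


def correlation_table(cohort: CohortTable, baseline_only: bool = False) -> pd.DataFrame:
    """Pearson TRR-HF correlation per scheme, pooling both timepoints.

    Pooling baseline + follow-up cases is the study convention; set
    ``baseline_only`` for the 8 baseline cases alone.
    """
    tp = "baseline" if baseline_only else None
    rows = []
    for scheme in SCHEME_KEYS:
        r, p = pearson(cohort.trr(scheme, tp), cohort.hf(scheme, tp))
        rows.append({"scheme": scheme, "reference": _REF_OF_SCHEME[scheme],
                     "n": len(cohort.hf(scheme, tp)), "r": r, "p": p})
    return pd.DataFrame(rows)
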