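# Methods

## Measurement model

A case consists of a 3D PET volume and co-registered binary ROI masks
(tumor; iliac-artery blood pool, *BP*; left-ventricle blood pool, *LV*;
gluteus maximus muscle, *GMc*; optionally bladder), all in NIfTI-1.
Masks drawn on a different grid (e.g. high-resolution MR) are propagated
onto the PET grid by nearest-neighbour resampling in world coordinates —
nearest-neighbour because it preserves binarity, which is the semantics
of propagating a contour. An empty propagated mask is an error, never a
silent success.

If the PET is in Bq/mL, body-weight SUV is computed as
`SUV = C·W/(D·2^(−t/T½))`, i.e. the injected dose is decay-corrected to
scan start before normalisation. Whether published SUVs are corrected to
injection or to scan time is generally not stated in clinical reports;
decay-to-scan is this package's convention, and `ScanMeta.half_life_min`
(default 109.77 min, ¹⁸F) is overridable.

### ROI statistics and thresholds

`roi_statistics` reports mean, **sample** SD (n−1 denominator; the
source tables print "SUVmean ± SD" without specifying, and the muscle
+3SD threshold inherits this choice), max, voxel count and volume. The
muscle mask is contracted by 4 mm (configurable) before statistics to
avoid partial-volume contaminated edge voxels. Contraction keeps exactly
the voxels whose Euclidean distance in mm (anisotropy-aware, computed by
the exact distance transform on voxel centres) to the mask complement is
≥ the radius — not a structuring-element erosion, which has no exact mm
meaning on anisotropic grids.

Thresholds: `f·SUVmean` (f = 1.0 or 1.2) for BP/LV, `SUVmean + 3·SD` for
GMc. A voxel is hypoxic when its SUV is **strictly greater** than the
threshold; the boundary convention is not stated in the source, and
strict inequality keeps voxels exactly at blood level oxic under the
×1.0 rule (switchable via `classify_voxels(strict=False)`).

### Bladder spill-in correction

Chronically hypoxic tumors show an approximately Gaussian SUV
distribution; spill-in from an adjacent hot bladder adds a positive
tail. The correction (a) fits the Gaussian background robustly — mean
from the histogram mode (Freedman–Diaconis binning, peak located on
3-bin-smoothed counts, apex refined by a quadratic fit to the
log-counts over the contiguous upper half of the peak, since the log of
a Gaussian is a parabola), width from the mirrored lower half,
`σ = sqrt(mean((x−μ)² for x ≤ μ))` — and (b) iteratively removes voxels
above `μ + k·σ` (default k = 3, max 10 iterations), refitting on the
retained set each round. Across 50 simulated samples of n = 10 000 the
mode estimator is accurate to ±0.008 SUV and moves by < 0.004 under 5 %
implanted contamination.

Two deliberate safeguards:

- the cut sequence is **monotonically non-increasing**
  (`cut_i = min(cut_{i−1}, μ_i + k·σ_i)`), so the retained set is
  exactly `{x ≤ final cut}`; every removed voxel exceeds the final cut,
  the procedure is idempotent by construction, and HF after correction
  can never exceed HF before at any fixed threshold;
- fitting is refused below 50 voxels (correction becomes a no-op with a
  warning, `SpillModel.applied = False`), and a removal that would leave
  fewer than 50 voxels stops the iteration with a `truncated` flag.

By default the corrected (retained) voxel set is also the HF
denominator: removed voxels are declared non-tumor signal and count in
neither numerator nor denominator (`RunConfig.hf_denominator =
"original"` restores the raw count for sensitivity analysis). The tumor
SUVmax used in TRR is taken after correction; otherwise bladder spill
would dominate the maximum. The raw SUVmax is reported alongside.

**Known limitation.** The truncation discriminates by *value* only. When
genuinely hypoxic uptake forms a mode well above `μ + k·σ` of the oxic
background — as in this package's default phantom, where hypoxic tissue
sits at twice the oxic level — the correction removes genuine hypoxia
along with spill, driving high-threshold HF estimates toward zero. On
real FAZA data hypoxic uptake is a continuum barely above blood level,
inside the Gaussian bulk the fit models, so this failure mode is far
milder; but it is the reason the validation suite evaluates correction
efficacy at the spill-sensitive low thresholds (below) and disables
correction on phantoms without a bladder. A unit test pins the
truncation-of-separated-modes behaviour so it cannot change silently.

### Cohort statistics

HF summaries are median (mid-mean for even n) and range. The TRR–HF
association uses Pearson product-moment correlation with the two-sided
t-transform p-value (df = n−2), pooling baseline and follow-up cases
(n = 12) as in the source analysis; a baseline-only mode exists.
Therapy-change metrics are ΔHF in percentage points and relative TRR
change `100·(post−pre)/pre`; the mean tumor-volume decrease is the mean
of per-patient percent changes (not the percent change of the mean),
which is the convention under which the printed 69.8 % reproduces.
Patients missing a timepoint are excluded listwise, never imputed.
Printed-table comparisons round half-away-from-zero to 1 decimal, the
convention of clinical tables; internal computation is full precision.

## Packaged cohort transcription

`hypofrac/data/study_cohort.csv` transcribes the published per-patient
measurements: tumor volume, SUVmax, tumor/GMc/BP/LV SUVmean ± SD, and HF
under the five schemes, for 8 baseline and 4 follow-up scans. The
published SUVmean block lists three sub-header labels over four value
columns; the four columns are read as (Tumor, GMc, BP, LV) — the reading
under which the muscle and LV correlations and the therapy-change spot
checks all reproduce.

Documented source discrepancies, reported but not asserted:

- the BP correlations (printed 0.344 and 0.611) are not recoverable from
  the printed per-patient tables under any column reading tried
  (recomputed: 0.579 and 0.779); the report prints both side by side;
- the source prints both 0.838 and 0.837 for the LV ×1.2 correlation;
- the summary-text HF minima for GMc+3SD (2.4) and LV ×1.0 (0.8)
  disagree with the per-patient table minima (0.5 and 0); the
  per-patient table is taken as the source of record;
- per-patient TRR changes recomputed from 2-decimal rounded inputs
  differ from print by up to ±0.8 points for some cells; each cell is
  flagged individually.

## Digital phantom

`generate_phantom` builds a 96×96×48 volume at 2.8 mm isotropic spacing:
an ellipsoidal tumor (semi-axes 20×17×14 mm, ≈ 20 mL) with a contiguous
hypoxic **cap** (a plane cut, sized to exactly the requested percentage
of tumor voxels — spatially coherent, as chronic hypoxia is, so PSF blur
produces realistic partial-volume mixing at the boundary); a 40 mm LV
sphere and an 8 mm iliac BP cylinder, both at blood level 1.2 (the
narrow cylinder deliberately suffers more partial-volume dilution,
mirroring why LV is the preferred blood reference); bilateral muscle
bodies at 0.9; soft-tissue background 0.8 (slightly below muscle,
typical of normoxic pelvic tissue); optionally a 25 mm-radius bladder at
SUV 10 abutting the tumor surface (offset configurable). Oxic and
hypoxic tumor voxels draw from N(1.0, 0.15) and N(2.0, 0.2) truncated at
the class midpoint 1.5 (≥ 2.5 SD out, so the distributions are
essentially unaltered) — each voxel's true class stays on its side of
the midpoint, making the true HF exactly recoverable when blur and noise
are off. The volume is convolved with an isotropic Gaussian PSF of
4.5 mm FWHM and Gaussian noise (SD 0.05 SUV) is added; noise is Gaussian
in SUV space, a post-reconstruction approximation, not Poisson in
counts. Masks are pre-blur ground truth. Everything is deterministic
given the seed.

`generate_cohort` draws per-case true HF uniformly (default 0–73 %, the
published baseline spread); paired patients get a follow-up with tumor
volume scaled by 0.3 (the ≈ 70 % post-therapy shrinkage) and an
independent HF.

### What the phantom shows — and does not

Validation results on the phantom (recomputed by the test suite and
`scripts/acceptance.py`):

- **Parameter recovery.** With no bladder and correction off, the
  LV ×1.2 pipeline estimate recovers true HF ∈ {0, 10, 30, 50, 70} %
  within ±1.5 points (5 seeds each; the tolerance asserted is ±5).
  LV ×1.2 is evaluated because it is the scheme the source study found
  most reliable; the low thresholds (muscle +3SD, blood ×1.0) sit inside
  the oxic SUV distribution and by design over-call hypoxia on this
  phantom, which is reference-scheme behaviour, not pipeline error.
- **Spill efficacy.** With the bladder abutting the tumor at true
  HF = 10 %, spill-in inflates the low-threshold schemes by +17 to +25
  points; correction moves both GMc+3SD and BP ×1.0 estimates closer to
  truth in 5/5 seeds. These schemes are the efficacy endpoints because a
  positive contamination tail biases thresholds near the background bulk
  the most — an analytic property, not an empirical selection. At
  LV ×1.2 spill barely registers (uncorrected error ≈ 0.3 points) and
  the correction's separated-mode limitation dominates instead (see
  above).
- **Reference fidelity.** LV and GMc means recover their assigned levels
  within 3 noise SDs; the BP cylinder reads ≈ 1.04 against an assigned
  1.2 — the designed partial-volume dilution, asserted as such.

The phantom does not model sinogram-level reconstruction, scatter or
attenuation artefacts, patient motion, heterogeneous (non-binary)
hypoxia gradients, or contouring error. Passing tests therefore show
the *quantification chain* is correct under controlled blur, noise and
spill — not that clinical HF values are accurate in any individual
patient.

## Problem sizes and tolerances

Phantom-based checks use the default 96×96×48 grid (~0.44 M voxels,
~900 tumor voxels), 5 seeds per condition. Numerical assertions: ROI
mean/SD agree with two-pass formulas to 1e-12; Pearson r matches the
textbook sum formula to 1e-10; erosion matches an exhaustive
distance-to-complement oracle voxel-for-voxel on ≤ 32³ grids (isotropic
and anisotropic); printed-value reproduction is exact after 1-decimal
half-away-from-zero rounding, correlations within ±0.02 (the printed
inputs are 2-decimal roundings).
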