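# hypofrac

Hypoxic-fraction quantification for ¹⁸F-FAZA PET/MR of rectal cancer.

Tumor hypoxia predicts poor response to chemo- and radiotherapy. With a
2-nitroimidazole tracer such as ¹⁸F-FAZA, hypoxic tumor voxels retain
tracer above the level of normally oxygenated tissue, so the **hypoxic
fraction** of a tumor can be estimated by thresholding its PET voxels
against a reference tissue. `hypofrac` implements that measurement chain
for PET/MR studies where the tumor is contoured on MR and the contour is
propagated onto PET:

- **SUV conversion** with radioactive-decay correction:
  `SUV(x) = C(x)·W / (D·2^(−t/T½))` for activity concentration `C`
  (Bq/mL), body weight `W` (g), injected dose `D` (Bq), uptake time `t`
  and half-life `T½` (109.77 min for ¹⁸F).
- **Reference thresholds**: a tumor voxel is hypoxic when
  `SUV > f · SUVmean(ref)` with `f ∈ {1.0, 1.2}` for a blood-pool
  reference (iliac artery *BP* or left ventricle *LV*), or
  `SUV > SUVmean + 3·SD` for gluteus-maximus muscle contracted by 4 mm
  (*GMc*). `HF = 100 · n_hypoxic / n_total` (% of tumor voxels).
- **Bladder spill-in correction**: tracer pooling in the urinary bladder
  blurs into adjacent tumor voxels, skewing the tumor SUV distribution
  positively. The tumor background is assumed Gaussian; a robust fit
  (histogram mode + mirrored lower-half width) followed by iterative
  truncation at `μ + k·σ` (default k = 3) removes the contaminated tail.
- **TRR** (`SUVmax(tumor) / SUVmean(ref)`), cohort summaries
  (median/range HF, Pearson TRR–HF correlation, therapy-change tables),
  and a **digital pelvic phantom** with known ground truth (ellipsoidal
  tumor with a contiguous hypoxic cap, reference organs, optional
  abutting hot bladder, 4.5 mm FWHM Gaussian PSF, additive noise) for
  validating every stage without patient data.

The package also ships a transcription of the published 8-patient cohort
(baseline + 4 follow-up scans after neoadjuvant chemoradiotherapy) and
recomputes its printed summary statistics.

## Worked example

Quantify one synthetic case with a known 30 % hypoxic fraction (no
bladder in the field):

```python
from hypofrac import CaseData, PhantomSpec, RunConfig, generate_phantom, run_case

pet, masks, truth = generate_phantom(PhantomSpec(true_hf=30, include_bladder=False, seed=42))
res = run_case(RunConfig(spill_enabled=False), CaseData(pet=pet, masks=masks))
print(res.to_frame(decimals=2)[["scheme", "threshold", "n_hypoxic", "n_total", "hf_percent", "trr"]])
```

```
  scheme  threshold  n_hypoxic  n_total  hf_percent  trr
GMC_+3SD       1.05        433      906       47.79 2.41
   BP_x1       1.04        436      906       48.12 2.08
   LV_x1       1.16        344      906       37.97 1.88
 BP_x1.2       1.25        295      906       32.56 2.08
 LV_x1.2       1.39        265      906       29.25 1.88
```

The LV ×1.2 scheme — the threshold the source study found most reliable —
recovers the true 30 % fraction (29.25 %). Lower thresholds sit inside
the oxic SUV distribution and intentionally over-call hypoxia; the
phantom makes that threshold dependence visible. `trr` is tumor SUVmax
over each reference's SUVmean.

The published cohort tables are reproduced with:

```bash
hypofrac published-tables
```

which prints each recomputed value beside its printed counterpart with a
match flag — e.g. baseline HF medians 16.6 / 36.8 / 30.7 / 10.4 / 4.3 %
(GMc+3SD, BP×1.0, LV×1.0, BP×1.2, LV×1.2), pooled TRR–HF Pearson r
0.243 / 0.510 / 0.831 against printed 0.241 / 0.499 / 0.838, and the
69.8 % mean tumor-volume decrease after therapy. The blood-pool (iliac)
correlations are reported but flagged: they are not recoverable from the
printed per-patient tables (see `docs/methods.md`).

Other CLI commands: `hypofrac simulate` (write a phantom cohort as NIfTI +
truth sidecars), `hypofrac quantify` (run the pipeline over case
directories), `hypofrac cohort` (summarize a results CSV).

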