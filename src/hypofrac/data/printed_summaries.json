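{
  "baseline_hf": {
    "GMc+3SD": {"median": 16.6, "min": 2.4, "max": 33.8},
    "BPx1.0": {"median": 36.8, "min": 0.3, "max": 72.9},
    "LVx1.0": {"median": 30.7, "min": 0.8, "max": 55.5},
    "BPx1.2": {"median": 10.4, "min": 0.0, "max": 47.6},
    "LVx1.2": {"median": 4.3, "min": 0.0, "max": 20.1}
  },
  "trr_hf_pearson_r": {
    "GMc+3SD": 0.241,
    "BPx1.0": 0.344,
    "LVx1.0": 0.499,
    "BPx1.2": 0.611,
    "LVx1.2": 0.838
  },
  "trr_hf_pearson_p": {
    "GMc+3SD": 0.45,
    "BPx1.0": 0.29,
    "LVx1.0": 0.09,
    "BPx1.2": 0.035,
    "LVx1.2": 0.0007
  },
  "asserted_correlations": ["GMc+3SD", "LVx1.0", "LVx1.2"],
  "trr_relative_change": {
    "GMc": {"P4": -47.7, "P5": -9.6, "P6": -15.9, "P10": 11.3},
    "BP": {"P4": -46.6, "P5": 13.7, "P6": -31.0, "P10": 15.8},
    "LV": {"P4": -54.0, "P5": 4.5, "P6": -30.5, "P10": 18.9}
  },
  "mean_volume_decrease_percent": 69.8,
  "notes": {
    "median_ranges": "Minima printed in the summary text for GMc+3SD (2.4) and LVx1.0 (0.8) differ from the per-patient table minima (0.5 and 0); the per-patient table is the source of record here.",
    "bp_correlations": "The BP correlations printed in the summary (0.344, 0.611) are not recoverable from the printed per-patient tables; recomputed values are reported beside them without an equality assertion.",
    "lv12_correlation": "The source prints both 0.838 and 0.837 for the LVx1.2 correlation; 0.838 is used for comparison."
  }
}
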