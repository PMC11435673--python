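patient_id,timepoint,volume_ml,tumor_suv_max,tumor_suv_mean,tumor_suv_sd,gmc_mean,gmc_sd,bp_mean,bp_sd,lv_mean,lv_sd,hf_gmc3sd,hf_bp10,hf_lv10,hf_bp12,hf_lv12
P4,baseline,41.43,1.96,0.94,0.19,0.86,0.10,0.92,0.09,0.93,0.10,11.8,57.6,55.5,18.6,15.4
P5,baseline,20.35,1.30,0.55,0.23,0.77,0.11,1.22,0.18,1.37,0.17,1.2,0.3,0,0,0
P6,baseline,22.88,1.43,0.74,0.17,0.84,0.11,0.67,0.06,0.80,0.11,0.5,66.3,40.2,38.1,7.2
P7,baseline,16.70,2.42,1.13,0.34,1.01,0.13,1.46,0.11,1.54,0.17,22.4,16.2,10.1,2.1,1.0
P8,baseline,18.80,2.88,3.14,2.56,1.18,0.19,1.21,0.22,1.43,0.18,21.3,33.4,21.5,27.0,20.1
P9,baseline,2.03,1.45,1.02,0.25,0.93,0.09,1.14,0.20,1.13,0.14,33.8,40.2,40.5,0.7,1.4
P10,baseline,6.05,1.45,0.88,0.17,0.89,0.12,1.35,0.20,1.34,0.22,2.4,0.3,0.8,0,0
P11,baseline,60.96,2.31,1.48,0.31,1.16,0.18,1.26,0.17,1.59,0.17,27.9,72.9,39.9,47.6,9.2
P4,followup,12.80,0.95,0.65,0.10,0.81,0.09,0.84,0.10,0.99,0.11,0,3.3,0,0.3,0
P5,followup,7.19,1.34,0.96,0.16,0.88,0.15,1.11,0.16,1.36,0.16,0.8,18.9,0,3.3,0
P6,followup,4.67,1.56,0.97,0.15,1.09,0.12,1.06,0.08,1.26,0.12,0.8,25.2,3.6,7.3,0.4
P10,followup,2.07,1.66,1.39,0.13,0.92,0.09,1.33,0.25,1.29,0.13,94.6,67.2,78.5,0,10.5
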