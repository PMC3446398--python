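# Demo simulation config: study-like defaults, small tissue cohort.
n_samples = 100
seed = 4
meas_cv = 0.10
n_reps = 3

[gene_effects]
# gene = [effect per low-expression haplotype (log2), residual SD]
SPP1 = [-0.80, 0.5]
MUC16 = [0.125, 0.05]
PAX8 = [-0.20, 0.2]
IGFBP5 = [0.15, 0.2]
BIRC5 = [0.0, 0.3]
RRM2 = [0.0, 0.3]

[carrier]
n = 2754
maf = 0.16
n_studies = 11
baseline_hazard = 0.02
censoring_scale = 70.0
# per-allele log hazard ratio: ln(0.85)
log_hr = -0.1625189294977749
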