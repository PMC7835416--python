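# Pipeline configuration for `nirkpls run --config examples/config.yaml`.
# Leave spectra_csv/reference_csv null to run on the synthetic dataset.

spectra_csv: null
reference_csv: null

# Synthetic-data overrides (defaults emulate the full campaign: 248
# samples, 188 bands, quadratic spectrum-analyte link).
synthetic: {}

# 2:1:1 calibration/validation/testing design.
split_sizes: [120, 64, 64]

# Kernel-width grid.  The exhaustive reference scan is 0.01..64 in steps
# of 0.01 (6,400 candidates); setting sigma_log_num switches to that many
# log-spaced widths between sigma_lo and sigma_hi, which is what routine
# runs use.
sigma_lo: 0.01
sigma_hi: 64.0
sigma_step: 0.01
sigma_log_num: 20

# Latent-variable range (s_max must not exceed n_cal - 1).
s_min: 1
s_max: 12

# Fit settings.
max_iter: 200
tol: 1.0e-10
literal_k: false

# Refinement-trace settings (Fig.-5-style curve).
trace_iterations: 200
trace_mode: restart

analytes: [SU, VC, OA]
seed: 1
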