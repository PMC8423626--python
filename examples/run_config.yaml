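# Full-pipeline configuration for `introscan run --config examples/run_config.yaml`.
# Omitted keys fall back to defaults; command-line flags override file values.
seed: 1
outdir: introscan_run
# simulator scenario (used because no input VCF is given)
pulse_proportion: 0.15
pulse_generation: 50
# published filter thresholds
min_depth: 4
min_gq: 5
min_maf: 0.05
max_missing: 0.1
max_het: 0.1
# scan geometry and roles
window_size: 10000
window_step: 5000
p1: G5
p2: G4
p3: G2
outgroup: OUT
target: G4
donor: G2
source: G5
fd_window_snps: 100
jackknife_block_snps: 500
ibd_min_snps: 50
ibd_min_bp: 100000
ibd_max_mismatch: 1
ribd_threshold: 0.7
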