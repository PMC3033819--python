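# A complete small run: simulate two species pools, then trim, map, call,
# screen, classify and scan for microsatellites. All thresholds default to
# the standard discovery protocol; only deviations need to be listed.
outdir: demo_run
rng_seed: 3

simulate:
  n_contigs: 4
  coverage_target: 40
  rng_seed: 3

# Example threshold overrides (defaults shown commented out):
# call:
#   min_depth: 4
#   min_variant_count: 2
#   min_central_quality: 25
#   min_flank_mean_quality: 20
#   min_maf: 0.10
#   clean_flank: 15
# align:
#   min_similarity: 0.80
#   min_length_fraction: 0.50
# trim:
#   min_mean_quality: 20
#   min_length: 15
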