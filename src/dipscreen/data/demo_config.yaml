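# Demo pipeline config: packaged 600-nt Gal4(1-147)-VP64 target, AsLOV2 insert.
# Sizes are kept small so run-all completes in well under a minute.
target_fasta: null        # packaged Gal4-VP64 synthetic CDS
domain_fasta: null        # packaged AsLOV2(408-543) synthetic CDS
tsd_len: 5
variant: LOV02
n_clones: 1500
reverse_fraction: 0.5
schedule: default         # three alternating dark-high / light-low rounds
n_rounds: 3
gate_quantile: 0.5
n_population: 50000
n_sorted: 10000
n_reads_per_round: 2500
fragment_len_range: [300, 400]
read_len: 300
per_base_error: 0.001
rules:
  switch_window: [20, 30]       # residues: functional insertions here photoswitch
  activation_domain_start: 149  # VP64 repeats begin after the Gal4 DBD
  gfp_high: 3000.0
  gfp_intermediate: 300.0
  floor: 10.0
  noise_cv: 0.6
out_dir: dipscreen_demo_run
seed: 0
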