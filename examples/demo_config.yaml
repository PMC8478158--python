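# Demo pipeline configuration.
# Generate the inputs first:
#   ddrcyto simulate --out sim --donors 2 --events 5000 --seed 1
# then run:
#   ddrcyto run --config examples/demo_config.yaml
input_dir: sim
output_dir: out
cofactor: 5.0
separation_cutoff: 0.3
min_events: 30
dna_band_mads: 3.0
stats_populations:
  - CD3+ T
  - CD56dim CD16+ NK
  - CD19+CD20+ B
seed: 1
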