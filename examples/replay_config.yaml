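# Full pipeline replay on a synthetic cohort with known causal architecture.
#   hlapqtl replay --config examples/replay_config.yaml --out run --seed 1
out_dir: run
seed: 1
simulate:
  n_individuals: 2000
  n_proteins: 10
catalog_path: examples/demo_catalog.json
n_perm: 200
max_positions: 3
maf_min: 0.01
r2_min: 0.7
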