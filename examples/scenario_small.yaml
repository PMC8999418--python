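# A small planted scenario for quick experiments:
#   ppibridge simulate --config examples/scenario_small.yaml --out-dir demo/sim
n_groups: 4
block_sizes: [14, 12, 12, 12]
n_disease_genes_per_block: [7, 6, 6, 6]
n_isolated_disease_genes: 4
bridges_per_isolated: 1
p_intra: 0.30
p_inter: 0.0
confidence_law: [uniform, 0.40, 0.95]
seed_fraction: 0.20
threshold: 0.40
rng_seed: 0
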