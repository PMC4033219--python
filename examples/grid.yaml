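# Reduced three-group experiment: one sample size, both subgroup ratios.
# Run with: subgroupsim run --config examples/grid.yaml --out results.csv
n_groups: 3
total_ns: [150]
nratios: [equal, unequal]     # unequal = 60/20/20 known-group ratio
sratios: [equal, unequal]     # unequal = 75/25 subgroup ratio
deltas: [0.2, 0.5, 0.8]
overlaps: [0.0, 0.05, 0.10, 0.15, 0.20]
methods: [lda, lr, mixda, cart, gam]
replicates: 100
master_seed: 7
method_config:
  mixda: {subclasses_per_class: 2}
  cart: {min_deviance_fraction: 0.01, min_node_size: 10}
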