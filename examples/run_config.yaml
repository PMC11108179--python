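# Demo pipeline configuration for `phenox run --config examples/run_config.yaml`
# Simulates a nitrate knockout panel after hypoxic pregrowth, generates a
# noisy synthetic plate, extracts LOWESS kinetics, and emits the pairwise
# Bonferroni significance matrix.
seed: 7
out_dir: phenox_out
acceptor: nitrate
pregrowth: hypoxic
genotypes: [wild_type, narG, napAnarZnarG, abiotic]
fraction: 0.05
threshold: 0.5
alpha: 0.05
method: welch
metric: max_rate
n_bio: 3
n_tech: 3
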