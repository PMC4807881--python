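kind: survival
seed: 1
reference_group: wildtype
groups:
  wildtype:
    n_individuals: 50
    n_replicates: 5
    lifespan: {median_days: 49, dispersion_days: 3}
  mutant:
    n_individuals: 50
    n_replicates: 5
    lifespan: {median_days: 23, dispersion_days: 6}
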