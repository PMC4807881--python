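kind: ovi
seed: 11
n_per_group: 10
groups:
  wildtype_like:
    n_vacuoles: [1, 2]
    vacuole_radius_um: [0.5, 1.0]
  mutant_like:
    n_vacuoles: [1, 2]
    vacuole_radius_um: [2.0, 2.6]
stats:
  alpha: 0.05
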