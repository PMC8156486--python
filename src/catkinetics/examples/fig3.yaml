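# Two-substrate / two-product reversible reaction S1 + S2 <-> S3 + S4 with
# steady-state prior Cat([alpha 0 0 1-alpha]) over the substrate pair,
# alpha = 1/4.  With the mean-field-corrected rate ratio
# beta = alpha^2/(1-alpha)^2 and substrates initially at maximum
# concentration, the substrates settle at a quarter of their maximum and
# the products at three quarters, while the free energy (a KL divergence to
# the model steady state) decreases monotonically.
schema_version: 1
kind: generative
species: [S1, S2, S3, S4]
factors:
  - children: [S1, S2]
    alpha: 0.25
  - children: [S3, S4]
    parents: [S1, S2]
    table:
      - [0.0, 0.0, 0.0, 1.0]
      - [0.0, 0.0, 0.0, 0.0]
      - [0.0, 0.0, 0.0, 0.0]
      - [1.0, 1.0, 1.0, 0.0]
simulation:
  t_max: 100.0
  n_points: 501
  initial: {S1: 1.0, S2: 1.0, S3: 0.0, S4: 0.0}
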