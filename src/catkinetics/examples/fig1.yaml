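# Three-state categorical system with a non-vanishing solenoidal component.
# Used to illustrate the Helmholtz-style split of the master equation into
# free-energy-conserving (solenoidal) and free-energy-descending
# (dissipative) flows.
schema_version: 1
kind: rate_matrix
rate_matrix:
  labels: [x1, x2, x3]
  rows:
    - [-2.0,  1.0,  0.5]
    - [ 1.5, -2.0,  1.0]
    - [ 0.5,  1.0, -1.5]
simulation:
  t_max: 12.0
  n_points: 241
  initial: {x1: 1.0, x2: 0.0, x3: 0.0}
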