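# Open enzymatic reaction S + E <-> C <-> P + E with constant substrate
# production and product removal at rate c (a non-equilibrium steady
# state).  alpha1 = alpha2 is the regime in which the implicit beliefs
# q~_S = alpha2 - q_P and q~_P = alpha2 - q_S converge to the true
# substrate and product marginals; z = 0.9 puts binding/unbinding on the
# fast timescale and catalysis on the slow one.  Initial conditions show
# the fast substrate/enzyme dip into complex followed by the slow rise of
# the product, and give the product-side free energy its transient
# increase while the substrate actively changes the enzyme concentration.
schema_version: 1
kind: enzymatic
enzymatic:
  alpha1: 0.8
  alpha2: 0.8
  z: 0.9
  c: 0.01
scale: {N: 1.0, V: 1.0, lam: 1.0}
simulation:
  t_max: 400.0
  n_points: 801
  # the substrate moiety u_S + u_C + u_P and the enzyme moiety u_E + u_C
  # are conserved; both must equal 1 to reach the model's steady state
  initial: {S: 0.5, E: 1.0, C: 0.0, P: 0.5}
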