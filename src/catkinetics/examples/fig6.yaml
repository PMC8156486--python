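# Seven-species metabolic network.  An external system supplies S3
# (sensory state) at a constant rate; the trunk S3 <-> S2 <-> S1 is
# reversible; two branches S1 -> S4 -> S5 and S1 -> S6 -> S7 drain through
# saturating effluxes on S5 and S7 (active states).  All reactions are
# Michaelis-Menten (enzymes absorbed by the quasi-equilibrium reduction).
# Lesioning S1_to_S4 (v_max -> 0) abolishes S4 and S5 and raises S2 and S6:
# a diaschisis, with the lost S5 output offset by increased S7 output.
schema_version: 1
kind: network
species: [S1, S2, S3, S4, S5, S6, S7]
reactions:
  - {id: S3_to_S2, kind: michaelis_menten, substrates: {S3: 1}, products: {S2: 1}, vmax: 1.0, km: 1.0}
  - {id: S2_to_S3, kind: michaelis_menten, substrates: {S2: 1}, products: {S3: 1}, vmax: 0.5, km: 1.0}
  - {id: S2_to_S1, kind: michaelis_menten, substrates: {S2: 1}, products: {S1: 1}, vmax: 1.0, km: 1.0}
  - {id: S1_to_S2, kind: michaelis_menten, substrates: {S1: 1}, products: {S2: 1}, vmax: 0.5, km: 1.0}
  - {id: S1_to_S4, kind: michaelis_menten, substrates: {S1: 1}, products: {S4: 1}, vmax: 1.0, km: 1.0}
  - {id: S4_to_S5, kind: michaelis_menten, substrates: {S4: 1}, products: {S5: 1}, vmax: 1.0, km: 1.0}
  - {id: S1_to_S6, kind: michaelis_menten, substrates: {S1: 1}, products: {S6: 1}, vmax: 1.0, km: 1.0}
  - {id: S6_to_S7, kind: michaelis_menten, substrates: {S6: 1}, products: {S7: 1}, vmax: 1.0, km: 1.0}
  - {id: S5_efflux, kind: michaelis_menten, substrates: {S5: 1}, products: {}, vmax: 1.0, km: 1.0}
  - {id: S7_efflux, kind: michaelis_menten, substrates: {S7: 1}, products: {}, vmax: 1.0, km: 1.0}
sources: {S3: 0.1}
sensory: [S3]
active: [S5, S7]
lesions: [S1_to_S4]
simulation:
  t_max: 200.0
  n_points: 401
  initial: {S1: 0.0, S2: 0.0, S3: 0.0, S4: 0.0, S5: 0.0, S6: 0.0, S7: 0.0}
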