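# Generic per-element Lennard-Jones parameters for protein (pseudo-)atoms.
#
# sigma in nm, epsilon in kcal/mol, charge in e.  These are coarse,
# element-level values for desk-scale interaction-energy demonstrations on
# synthetic systems; production analyses should supply the per-atom-type
# parameters of the force field that generated the trajectory.
combination_rule: lorentz-berthelot
species:
  C: {sigma: 0.3500, epsilon: 0.0660, charge: 0.0}
  N: {sigma: 0.3250, epsilon: 0.1700, charge: 0.0}
  O: {sigma: 0.2960, epsilon: 0.2100, charge: 0.0}
  S: {sigma: 0.3560, epsilon: 0.2500, charge: 0.0}
  H: {sigma: 0.2500, epsilon: 0.0300, charge: 0.0}
  X: {sigma: 0.3500, epsilon: 0.0660, charge: 0.0}
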