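# Provisional nonbonded parameters for a rigid 2H-MoS2 monolayer.
#
# sigma in nm, epsilon in kcal/mol, charge in e.  These are literature-style
# placeholder values for a neutral sheet (q_Mo + 2*q_S = 0) and are meant to
# be REPLACED by the parameter set of the force field actually used for a
# production system.  Nothing in the analysis code depends on these numbers.
combination_rule: lorentz-berthelot
species:
  Mo:
    sigma: 0.4200
    epsilon: 0.0135
    charge: 0.600
  S:
    sigma: 0.3130
    epsilon: 0.4612
    charge: -0.300
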