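# Metal registry for naphthenate composition and risk assessment.
# Atomic weights: CIAAW conventional values. MRLs in mg/kg/day.
metals:
  - symbol: Cu
    name: copper
    atomic_weight: 63.546
    oxidation_state: 2
    mrl: 0.01
    mrl_duration: acute/intermediate
    mrl_basis: ATSDR copper profile (2004)
  - symbol: Zn
    name: zinc
    atomic_weight: 65.38
    oxidation_state: 2
    mrl: 0.3
    mrl_duration: intermediate
    mrl_basis: ATSDR zinc profile (2005)
  - symbol: Co
    name: cobalt
    atomic_weight: 58.933
    oxidation_state: 2
    mrl: 0.01
    mrl_duration: intermediate
    mrl_basis: ATSDR cobalt profile (2004)
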