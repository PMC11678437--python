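# Six-state cohort model of child wasting and stunting for the Colombian
# 2021 birth cohort. The newborn row is a one-shot allocation at t = 0, not
# a persistent state: nothing transitions back into it.
states: [adequate_weight, low_birth_weight, wasting, stunting, wasting_stunting, death]
absorbing: [death]
newborn_row_label: newborn
cohort_size: 512611
n_cycles: 4
row_tolerance: 1.0e-3
newborn_split:
  adequate_weight: 0.8988
  low_birth_weight: 0.1012
transitions:
  adequate_weight:
    {adequate_weight: 0.8932, low_birth_weight: 0.0, wasting: 0.0120,
     stunting: 0.0820, wasting_stunting: 0.0010, death: 0.0118}
  low_birth_weight:
    # row sums to 1.0001 as published (4-decimal rounding); renormalized on load
    {adequate_weight: 0.7685, low_birth_weight: 0.0, wasting: 0.0280,
     stunting: 0.1580, wasting_stunting: 0.0280, death: 0.0176}
  wasting:
    {adequate_weight: 0.6400, low_birth_weight: 0.0, wasting: 0.1382,
     stunting: 0.1890, wasting_stunting: 0.0070, death: 0.0258}
  stunting:
    # kept as published, including the large stunting -> wasting mass
    {adequate_weight: 0.0, low_birth_weight: 0.0, wasting: 0.9348,
     stunting: 0.0108, wasting_stunting: 0.0463, death: 0.0081}
  wasting_stunting:
    {adequate_weight: 0.3000, low_birth_weight: 0.0, wasting: 0.0,
     stunting: 0.4990, wasting_stunting: 0.1671, death: 0.0339}
  death:
    {adequate_weight: 0.0, low_birth_weight: 0.0, wasting: 0.0,
     stunting: 0.0, wasting_stunting: 0.0, death: 1.0}
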