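# Burden parameters for the Colombia fixture. Disability weights are
# GBD-2019-sourced in the original analysis but never published numerically,
# and the life expectancy used is likewise unpublished: both are therefore
# left null ("to be calibrated") and back-solved against the published
# burden table rather than invented.
life_expectancy: null        # Colombian official life expectancy, user-supplied
disability_weights:
  wasting: null
  stunting: null
  wasting_stunting: null
age_at_death_convention: mid_cycle     # AD_t = t - 0.5 years
age_of_onset_convention: cycle_start
duration_convention: prevalent_year    # 1 year of YLD per prevalent person-cycle
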