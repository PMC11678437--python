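# Cost schedules for the Colombia fixture (all engine arithmetic in USD 2023).
# Inflation factors are config inputs, given here as the ratios implied by the
# published source-year / 2023 cost pairs.
currency: USD
target_year: 2023
inflation_factors:
  - {from_year: 2019, to_year: 2023, factor: 1.369471181391}   # ARI 698.16 -> 956.11
  - {from_year: 2015, to_year: 2023, factor: 1.641634980989}   # ADD 52.60 -> 86.35
  - {from_year: 2021, to_year: 2023, factor: 0.820720045672}   # therapy 560.52 -> 460.03
  - {from_year: 2023, to_year: 2023, factor: 1.0}
schedules:
  wasting:
    # ARI/ADD composition weights used as published (0.42 + 0.53, not renormalized)
    payer_split: {system: 1.0, household: 0.0}
    active_cycles: [1, 2, 3, 4]
    components:
      - {weight: 0.42, amount: 698.16, price_year: 2019, description: "ARI episode"}
      - {weight: 0.53, amount: 52.60, price_year: 2015,
         description: "ADD rehydration + high-complexity hospitalization"}
  stunting:
    # amount is already the health-system share: one of three weekly
    # occupational-therapy sessions (~33%); active from age two
    payer_split: {system: 1.0, household: 0.0}
    active_cycles: [3, 4]
    components:
      - {weight: 1.0, amount: 560.52, price_year: 2021,
         description: "occupational therapy, subsidized session"}
  wasting_stunting:
    # assumed equal to the maximum of the wasting and stunting costs
    payer_split: {system: 1.0, household: 0.0}
    active_cycles: [3, 4]
    max_of: [wasting, stunting]
indirect:
  # per-person per-cycle household OOP by state; unpublished, so empty here:
  # target-mode back-solves the implied values from the published cost table
  household_costs: {}
  therapy_addon:
    amount: 920.0            # USD/yr, the ~67% of therapy borne by households
    states: [stunting, wasting_stunting]
    active_cycles: [3, 4]
poverty:
  currency: COP
  months_per_year: 12
  monthly_lines: {extreme: 198698.0, monetary: 396864.0}   # COP/month, 2022
  exchange_rate_cop_per_usd: null                          # unpublished
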