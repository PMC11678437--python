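# Published caregiver-survey summary statistics (n = 43, Antioquia, 2023-24).
# These are the distributional targets the synthetic survey generator emulates.
n_records: 43
oop_category_means:            # USD per year, recurring categories
  transportation: 451.76
  food: 225.88
  stationery: 84.71
hospitalization_episode_mean: 971.89   # USD per episode, kept separate (not annualized)
per_capita_annual_expenditure: 162.98
household_income_mean: 352.21          # USD per month
per_capita_income_mean: 190.34
wasting_share: 0.7619
income_decreased_share: 0.381
strata_shares: {"1": 0.558, "2": 0.352, "3": 0.09}
insurance_shares: {subsidized: 0.744, contributory: 0.233, uninsured: 0.023}
area_shares: {urban: 0.628, rural: 0.372}
caregiver_mother_share: 0.9535
caregiver_mean_age: 37.0
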