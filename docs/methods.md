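# Methods

## Cohort model

The model is a discrete-time, time-homogeneous Markov chain over six
mutually exclusive health states — adequate weight, low birth weight
(BPN), wasting (acute malnutrition), stunting (chronic malnutrition), the
combined wasting + stunting state, and death — with death the single
absorbing state. Cycle length is one year; cycles t = 1..4 correspond to
ages 0–1 through 3–4, matching a burden horizon of the first four years
of life. The published transition table carries a seventh row for
newborns (RN); no state transitions back into it, so it is treated as a
one-shot allocation at t = 0 (89.88% adequate weight, 10.12% low birth
weight) rather than a persistent state, and the persistent chain stays
six-state.

Occupancy propagates as `M^(n+1) = M^n P`. Fractional persons are carried
exactly throughout; rounding happens only when tables are written
(2 decimals for burden, money and per-1000 values; integer percent for
shares). There is no half-cycle correction, and all accrual (burden and
cost) uses end-of-cycle occupancy `M^t`; this is recorded explicitly so
that costing is reproducible.

**Row validation.** Published matrices are rounded to four decimals; one
row of the bundled matrix sums to 1.0001. Rows within `row_tolerance`
(default 1e-3) of 1 are accepted with a warning and renormalized by
dividing by the row sum, after which each row sums to 1 within 1e-12.
Larger deviations, entries outside [0, 1], or an absorbing row that is
not an exact unit self-loop fail validation. The large stunting → wasting
probability (0.9348) in the published table is used exactly as printed —
it may be a column-ordering artifact in the source, but no "correction"
is applied. The newborn row assigns zero probability to death, implying
no neonatal deaths before first allocation; this too is kept as
published.

**Oracle.** `occupancy_by_power` computes `M^0 P^n` by explicit matrix
exponentiation and is held to agree with iterative simulation to 1e-9
relative; the property is exercised over 100 random row-stochastic
matrices (k ≤ 8, n ≤ 20) at a fixed seed.

## Burden (DALY) engine

Per cycle: `YLL_t = deaths_t × (LE − AD_t)` and
`YLD_t = Σ_s occ_t(s) × DW(s) × D`, with `DALY = YLL + YLD` and per-1000
normalization by the initial cohort size. One widely printed form of the
YLL definition carries the sign as (AD − LE), which is negative for child
deaths; the engine implements the standard LE − AD.

Default conventions, all config-overridable:

* `AD_t = t − 0.5` — deaths occur mid-cycle;
* disability duration `D` = 1 year per prevalent person-cycle (onset at
  cycle start);
* no discounting and no age weighting, consistent with GBD-2019 practice;
* deaths contribute YLL only within the four modeled cycles.

**Parameters.** `LE` is the national life expectancy in years; `DW(s)` is
a severity weight in [0, 1] per disabled state (wasting, stunting,
combined). The package ships no invented defaults for either: the
bundled config marks them "to be calibrated" because the source analysis
cites GBD 2019 and national statistics without printing the numbers.

**Calibration.** `calibrate_params` back-solves any subset of
{LE, death-age offset, DW map} from a target burden table. The forward
model is linear in every one of these, so the fit is a bounded linear
least squares on relative residuals (`scipy.optimize.lsq_linear`, DW
bounded to [0, 1]): deterministic, globally optimal, no multi-start
needed. Identifiability is checked from the design (cycles with deaths;
rank of the disabled-occupancy matrix), and a per-cell residual report is
always returned. Freeing LE and the offset together leaves only their sum
identified; the minimum-norm solution is returned.

On the bundled fixture the YLD column is internally consistent: three
weights (≈ 0.143 wasting, 0.032 stunting, 0.759 combined — plausible
magnitudes for moderate/severe malnutrition sequelae) reproduce all four
published YLD cells to within 0.2%. The published YLL column is *not*
consistent with any single LE under the mid-cycle convention (the implied
LE − AD_t per cycle is 1.44, 9.13, 8.82, 8.95 years), so the LE fit
reports large residuals; this is a property of the source table, surfaced
honestly in the calibration report rather than hidden. Exact forward
reproduction of the published burden table is therefore not claimed;
aggregation of its printed per-cycle cells (totals, DALY additivity,
per-1000) is reproduced exactly.

## Cost engine

All arithmetic is in a single currency (USD, 2023 prices). Unit costs
carry a price year and are standardized with configurable multiplicative
inflation factors; the bundled factors are the ratios implied by the
published source-year/2023 cost pairs (deriving factors from official CPI
series is out of scope).

* **Wasting** blends an acute-respiratory-infection episode cost
  (USD 956.11) and an acute-diarrheal-disease cost (USD 86.35) with
  incidence weights 0.42 and 0.53 *as published* — they sum to 0.95 and
  are deliberately not renormalized, giving USD 447.33 per person-cycle.
* **Stunting** costs USD 460.03 per person-cycle, the health-system third
  of thrice-weekly occupational therapy, active only in cycles 3–4
  ("from the age of two up to four years").
* **The combined state** takes the maximum over the individual cost items
  of the referenced states (USD 956.11), also active in cycles 3–4, and
  is treated as stunted for the household therapy add-on.
* **Indirect costs** are per-person household amounts per state plus a
  fixed USD 920/yr therapy add-on (the household two-thirds of therapy)
  for stunted and combined states from cycle 3 onward.

Costing is prevalence-based (per person-cycle of occupancy), matching the
annual-cost framing of the unit-cost sources. Known inconsistencies in
the source are preserved rather than resolved: full annual therapy
implied by the direct side is ≈ 460.03/0.33 ≈ 1,394 USD but by the
household side ≈ 920/0.67 ≈ 1,373 USD; and the published direct-cost
column sums to 2.36 USD above its own printed total (printed rounding),
which is why table comparisons use an absolute tolerance class of ±2.5
for that cell versus ±0.02 for exact-aggregation cells.

The per-person indirect inputs behind the published cost table were never
released, so target mode back-solves the implied per-person household
cost per cycle (subtract the therapy add-on, divide by costed occupancy)
and logs it for audit: on the fixture the implied values rise from
≈ USD 18 to ≈ USD 140 per person-year across the four cycles.

Poverty comparison: annual out-of-pocket spending divided by twelve times
a monthly per-capita poverty line, as a percentage. The 2022 Colombian
lines (COP 198,698 extreme; COP 396,864 monetary) are bundled; the COP
numerator and exchange rate behind the published 123.4%/61.8% figures
were not released, so the fixture leaves the numerator unset and the
operation is generic. The published shares themselves are cross-checked
only through the algebraic identity that their ratio equals the inverse
ratio of the lines (≈ 1.997).

## Survey summarization

Caregiver-survey records (income, out-of-pocket categories, demographics)
are summarized as means over non-missing values and categorical shares
over non-missing denominators, with exclusion counts always reported. No
imputation is performed — at n = 43 it would invent structure. The
hospitalization cost is per episode and is never annualized into the
recurring categories. Both household-level and per-capita annual
expenditure are reported, since the household-size divisor linking them
in the source is unstated. Category ranking sorts by descending mean with
alphabetical tie-breaks.

## Synthetic data

The generators emulate the statistical structure the pipeline assumes,
not any real dataset:

* **Matrices** — unmasked entries of each row are flat-Dirichlet on the
  simplex (the simplest exchangeable choice), structural zeros follow the
  six-state topology (no return to low birth weight, death absorbing).
* **Burden scenarios** — a simulated trace plus the burden table its
  known parameters imply; defaults LE = 76 y and DW = {0.05, 0.10, 0.15},
  with recovery tests drawing LE from [60, 85] and DW from [0.02, 0.8] as
  realistic GBD-like ranges. Because table and trace come from the same
  forward model, calibration must recover the parameters exactly (within
  1% in the acceptance property, in practice to machine precision) — a
  round-trip oracle, not evidence about real tables.
* **Surveys** — expenditures and incomes are lognormal (right-skewed,
  nonnegative; sigma default 0.75) with the mean matched to the published
  category means via `mu = log(mean) − sigma²/2`; categoricals draw from
  the published share vectors. Passing the 2% mean-recovery check at
  n = 10,000 shows the generator and summarizer are consistent; it says
  nothing about sampling error at the real n = 43.

Everything is deterministic under a seed (`numpy.random.default_rng`).

## Problem sizes

The default test and acceptance runs use the fixture cohort (512,611
persons, 4 cycles — a vector-matrix recursion, milliseconds), 100 random
chains for the oracle property, 20 synthetic calibration scenarios, and
10,000 synthetic survey records; the whole suite completes in seconds.

## Known limitations

* No individual-level microsimulation, time-inhomogeneous matrices, or
  probabilistic sensitivity analysis (the engine is an extension point).
* No comorbidity adjustment of disability weights; no uncertainty
  intervals on DALYs.
* No survey weighting or inference beyond the convenience sample.
* A second published cost table repeats the main one with every cell
  smaller by a constant factor ≈ 235.29 with no stated denominator; it is
  not modeled. Published texts also disagree internally on the payer
  shares (65% household in one place, 68% health system in another); the
  engine reports computed shares (65% indirect on the published columns).
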