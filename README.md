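# malnutburden

Burden-of-disease and cost-of-illness pipeline for child wasting and
stunting, built around the Colombian analysis of the 2021 birth cohort
(512,611 live births followed over the first four years of life).

The package is aimed at health economists and epidemiologists who need a
tested, reproducible implementation of the three stages of such a study:

1. **Markov cohort model** (`malnutburden.markov`) — a closed cohort is
   propagated through annual cycles of a six-state discrete-time Markov
   chain (adequate weight, low birth weight, wasting, stunting, combined
   wasting + stunting, and absorbing death) by
   `M^(n+1) = M^n P`, with a one-shot newborn allocation row, row-sum
   validation/renormalization for published rounded matrices, and an
   independent matrix-power oracle.
2. **DALY engine** (`malnutburden.burden`) — per cycle `t`,
   `YLL_t = deaths_t (LE − AD_t)` with mid-cycle deaths `AD_t = t − 0.5`,
   `YLD_t = Σ_s occ_t(s) · DW(s)` over the disabled states, and
   `DALY = YLL + YLD`, normalized per 1000 cohort members. Unpublished
   parameters (life expectancy LE, GBD-style disability weights DW) are
   never invented: a deterministic bounded linear least-squares
   calibration back-solves them from a target burden table and reports
   per-cell residuals.
3. **Cost engines** (`malnutburden.costs`, `malnutburden.survey`) —
   direct health-system costs from per-state unit-cost schedules
   (composition weights, inflation standardization to 2023 USD, payer
   splits, a max-cost rule for the combined state, therapy active only
   from age two) and indirect household costs (per-person out-of-pocket
   inputs plus a fixed USD 920/yr therapy add-on), with totals, payer
   shares, and poverty-line comparisons; caregiver-survey records are
   summarized into the category means and demographic shares that feed
   the indirect inputs.

`malnutburden.synthetic` generates random valid transition matrices,
forward-computed burden scenarios (the oracle for calibration), and
lognormal caregiver-survey samples, so the whole pipeline is testable
without any external data. `malnutburden.colombia` ships the published
parameterization (transition table, unit costs, burden and cost tables,
survey summaries) as plain-text fixtures.

## Worked example

Run the bundled Colombian fixture in target mode (published per-cycle
tables as inputs; unpublished parameters back-solved and logged):

```python
from pathlib import Path
from malnutburden import colombia
from malnutburden.pipeline import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(
    model=colombia.model_path(),
    burden=colombia.burden_path(),
    costs=colombia.costs_path(),
    out_dir=Path("out"),
    mode="target",
    burden_target=colombia.burden_table_path(),
    cost_target=colombia.cost_table_path(),
))
print(summary)
```

which prints (cohort of 512,611; 4 annual cycles):

```
{'cohort_size': 512611.0, 'n_cycles': 4,
 'yll_total': 178272.73, 'yld_total': 36944.18, 'daly_total': 215216.91,
 'daly_per_1000': 419.84,
 'total_direct': 128919091.77, 'total_indirect': 243576094.11,
 'grand_total': 372495185.88,
 'share_direct_pct': 35, 'share_indirect_pct': 65}
```

Read: the cohort loses 419.84 disability-adjusted life years per 1000
children over its first four years; the four-year societal cost is
USD 372.50 million in 2023 prices, 65% of it borne by households and 35%
by the health system. `out/run.log` records the back-solved disability
weights (≈ 0.143 wasting, 0.032 stunting, 0.759 combined — the three
weights reproduce the published YLD column to within 0.2%) and the
implied per-person household costs per cycle; `out/burden_table.csv` and
`out/cost_table.csv` mirror the published tables.

The same pipeline is scriptable from the shell:

```sh
malnut-burden simulate --model src/malnutburden/fixtures/colombia_model.yaml --out out/
malnut-burden synth survey --seed 7 --n-records 43 --out out/
malnut-burden survey-summarize --in out/survey.csv --out out/summary/
```

## Limitations

Full forward reproduction of the published burden and cost tables from
the transition matrix alone is not claimed: the published YLL column is
mutually inconsistent with any single life expectancy under the stated
conventions, and the per-person indirect inputs behind the published cost
table were never released. Target mode therefore aggregates the published
per-cycle cells exactly while back-solving and auditing the unpublished
parameters. See `docs/methods.md` for the model conventions, calibration
details and known inconsistencies in the source tables.
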