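"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators, all deterministic under a seed:

* random row-stochastic transition matrices honoring a structural-zero
  mask (unmasked entries are flat-Dirichlet on the row simplex, the
  absorbing state a unit self-loop);
* forward-generated burden scenarios — a simulated trace plus the burden
  table its known life expectancy and disability weights imply — used as
  round-trip oracles for the calibration routine;
* caregiver-survey records with right-skewed (lognormal) expenditure
  categories matched to target means and categorical fields drawn from
  target share vectors.

Survey generator defaults follow the published summary statistics of the
43-caregiver Antioquia survey (category means 451.76 / 225.88 / 84.71
USD/yr, hospitalization 971.89 USD/episode, incomes 352.21 / 190.34
USD/month, 74.4/23.3/2.3% insurance regimes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .burden import BurdenParams, BurdenTable, aggregate_daly, compute_yld, compute_yll
from .markov import (
    CohortTrace,
    NewbornAllocation,
    StateSpace,
    TransitionMatrix,
    simulate,
)

__all__ = ["ScenarioSpec", "gen_matrix", "gen_burden_scenario", "gen_survey"]

_DEFAULT_STATES = (
    "adequate_weight",
    "low_birth_weight",
    "wasting",
    "stunting",
    "wasting_stunting",
    "death",
)

# lognormal mean = exp(mu + sigma^2/2)  =>  mu = log(mean) - sigma^2/2
def _lognormal_mu(mean: float, sigma: float) -> float:
    return np.log(mean) - sigma**2 / 2.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Everything a synthetic scenario needs, keyed by a single seed."""

    seed: int = 0
    states: tuple[str, ...] = _DEFAULT_STATES
    absorbing: tuple[str, ...] = ("death",)
    # structural zeros: forbidden (from, to) transitions beyond the absorbing rows
    forbidden: tuple[tuple[str, str], ...] = (
        ("adequate_weight", "low_birth_weight"),
        ("wasting", "low_birth_weight"),
        ("stunting", "low_birth_weight"),
        ("wasting_stunting", "low_birth_weight"),
        ("low_birth_weight", "low_birth_weight"),
    )
    cohort_size: float = 512_611.0
    n_cycles: int = 4
    newborn_split: Mapping[str, float] = field(
        default_factory=lambda: {"adequate_weight": 0.8988, "low_birth_weight": 0.1012}
    )
    life_expectancy: float = 76.0
    disability_weights: Mapping[str, float] = field(
        default_factory=lambda: {"wasting": 0.05, "stunting": 0.10, "wasting_stunting": 0.15}
    )
    # survey generation
    oop_means: Mapping[str, float] = field(
        default_factory=lambda: {
            "transportation": 451.76,
            "food": 225.88,
            "stationery": 84.71,
            "other": 50.0,
        }
    )
    hospitalization_episode_mean: float = 971.89
    income_means: tuple[float, float] = (352.21, 190.34)  # household, per-capita USD/month
    lognormal_sigma: float = 0.75
    categorical_shares: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "child_status": {"wasting": 0.7619, "stunting": 0.16, "both": 0.0781},
            "stratum": {"1": 0.558, "2": 0.352, "3": 0.09},
            "area": {"urban": 0.628, "rural": 0.372},
            "insurance": {"subsidized": 0.744, "contributory": 0.233, "uninsured": 0.023},
            "caregiver_relationship": {
                "mother": 0.9535, "father": 0.02, "grandparent": 0.02, "other": 0.0065
            },
            "caregiver_head_of_household": {"no": 0.65, "yes": 0.35},
            "income_decreased": {"yes": 0.381, "no": 0.619},
        }
    )

    def space(self) -> StateSpace:
        return StateSpace(names=self.states, absorbing=frozenset(self.absorbing))


def gen_matrix(spec: ScenarioSpec) -> TransitionMatrix:
    """Random row-stochastic matrix honoring the structural-zero mask.

    Each non-absorbing row is a flat Dirichlet draw over its allowed
    columns; absorbing rows are exact unit self-loops.  Deterministic
    under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    space = spec.space()
    k = space.k
    allowed = np.ones((k, k), dtype=bool)
    for a, b in spec.forbidden:
        allowed[space.index(a), space.index(b)] = False
    P = np.zeros((k, k))
    for i, name in enumerate(space.names):
        if name in space.absorbing:
            P[i, i] = 1.0
            continue
        cols = np.flatnonzero(allowed[i])
        if cols.size == 0:
            raise ValueError(f"mask forbids every transition out of {name!r}")
        if cols.size == 1:
            P[i, cols[0]] = 1.0
        else:
            P[i, cols] = rng.dirichlet(np.ones(cols.size))
    return TransitionMatrix(P, row_tolerance=1e-9)


def gen_burden_scenario(
    spec: ScenarioSpec,
) -> tuple[CohortTrace, BurdenTable, BurdenParams]:
    """Forward-generate a trace and the burden table its known parameters imply.

    The returned table is exactly the forward model's output, so inverting
    it with the calibration routine must recover ``params`` — the
    generator is the oracle.
    """
    space = spec.space()
    matrix = gen_matrix(spec)
    alloc = NewbornAllocation(cohort_size=spec.cohort_size, split=dict(spec.newborn_split))
    trace = simulate(alloc, matrix, space, spec.n_cycles)
    params = BurdenParams(
        life_expectancy=spec.life_expectancy,
        disability_weights=dict(spec.disability_weights),
    )
    table = aggregate_daly(
        compute_yll(trace, params), compute_yld(trace, params), spec.cohort_size
    )
    return trace, table, params


def gen_survey(spec: ScenarioSpec, n_records: int) -> pd.DataFrame:
    """Synthetic caregiver-survey records.

    Expenditures and incomes are lognormal with means matched to the
    targets (right-skewed, nonnegative, sigma = ``spec.lognormal_sigma``);
    categorical fields are drawn from the target share vectors.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    rng = np.random.default_rng(spec.seed)
    sigma = spec.lognormal_sigma
    df = pd.DataFrame(index=range(n_records))
    for cat, mean in spec.oop_means.items():
        df[f"oop_{cat}"] = rng.lognormal(_lognormal_mu(mean, sigma), sigma, n_records)
    df["oop_hospitalization_episode"] = rng.lognormal(
        _lognormal_mu(spec.hospitalization_episode_mean, sigma), sigma, n_records
    )
    hh_mean, pc_mean = spec.income_means
    df["household_income"] = rng.lognormal(_lognormal_mu(hh_mean, sigma), sigma, n_records)
    df["per_capita_income"] = rng.lognormal(_lognormal_mu(pc_mean, sigma), sigma, n_records)
    for col, shares in spec.categorical_shares.items():
        levels = list(shares)
        p = np.array([shares[l] for l in levels], dtype=float)
        df[col] = rng.choice(levels, size=n_records, p=p / p.sum())
    df["caregiver_age"] = np.clip(rng.normal(37.0, 8.0, n_records), 16, 80).round(0)
    df["household_size"] = rng.integers(2, 8, n_records)
    return df
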