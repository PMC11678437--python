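"""Caregiver-survey summarization feeding the indirect-cost inputs.

Records describe households of children treated for wasting and/or
stunting: annual out-of-pocket (OOP) spending by category, a per-episode
hospitalization cost, monthly incomes, socioeconomic stratum, insurance
regime, area, and caregiver attributes.  Summaries are simple means and
categorical shares computed pairwise over non-missing values — no
imputation, the samples involved are tiny — with exclusion counts always
reported.  The hospitalization cost is an episode cost and is kept apart
from the annual recurring categories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OOP_CATEGORIES",
    "CATEGORICAL_COLUMNS",
    "SurveySummary",
    "read_survey",
    "summarize",
    "rank_categories",
    "write_summary",
]

#: annual recurring out-of-pocket categories (USD/yr)
OOP_CATEGORIES = ("transportation", "food", "stationery", "other")
#: per-episode cost, not annualized
EPISODE_COLUMN = "oop_hospitalization_episode"
#: closed-vocabulary categorical columns summarized as shares
CATEGORICAL_COLUMNS = {
    "child_status": ("wasting", "stunting", "both"),
    "stratum": ("1", "2", "3", "4", "5", "6"),
    "area": ("urban", "rural"),
    "insurance": ("subsidized", "contributory", "uninsured"),
    "caregiver_relationship": ("mother", "father", "grandparent", "other"),
    "caregiver_head_of_household": ("yes", "no"),
    "income_decreased": ("yes", "no"),
}
NUMERIC_COLUMNS = (
    tuple(f"oop_{c}" for c in OOP_CATEGORIES)
    + (EPISODE_COLUMN, "household_income", "per_capita_income",
       "caregiver_age", "household_size")
)


@dataclass(frozen=True)
class SurveySummary:
    """Means, shares and missing-data accounting for a set of survey records."""

    n_records: int
    oop_means: Mapping[str, float]               # category -> mean annual USD
    hospitalization_episode_mean: float | None
    household_income_mean: float | None          # USD/month
    per_capita_income_mean: float | None
    household_annual_oop_mean: float | None      # sum of recurring categories
    per_capita_annual_oop_mean: float | None     # divided by household size
    caregiver_age_mean: float | None
    shares: Mapping[str, Mapping[str, float]]    # variable -> level -> percent
    missing_counts: Mapping[str, int] = field(default_factory=dict)


def read_survey(path: str | Path) -> pd.DataFrame:
    """Read a survey CSV and validate its column dictionary and vocabularies."""
    df = pd.read_csv(path, dtype={"stratum": "string"})
    missing_cols = [c for c in NUMERIC_COLUMNS + tuple(CATEGORICAL_COLUMNS) if c not in df]
    if missing_cols:
        raise ValueError(f"survey file missing columns: {missing_cols}")
    for col in NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="raise")
        if col != "caregiver_age" and (df[col].dropna() < 0).any():
            raise ValueError(f"negative values in {col}")
    for col, vocab in CATEGORICAL_COLUMNS.items():
        bad = set(df[col].dropna().astype(str)) - set(vocab)
        if bad:
            raise ValueError(f"{col} contains values outside its vocabulary: {sorted(bad)}")
    return df


def _mean(series: pd.Series) -> float | None:
    s = series.dropna()
    return float(s.mean()) if len(s) else None


def summarize(records: pd.DataFrame) -> SurveySummary:
    """Compute category means, income means and categorical shares.

    Means use non-missing values per field; shares use non-missing
    denominators per variable; exclusion counts are reported per column.
    """
    if len(records) == 0:
        raise ValueError("cannot summarize an empty survey")
    oop_means = {c: _mean(records[f"oop_{c}"]) for c in OOP_CATEGORIES}
    recurring = records[[f"oop_{c}" for c in OOP_CATEGORIES]].sum(axis=1, min_count=1)
    per_capita = recurring / records["household_size"]
    shares: dict[str, dict[str, float]] = {}
    for col in CATEGORICAL_COLUMNS:
        obs = records[col].dropna().astype(str)
        if len(obs):
            shares[col] = (obs.value_counts(normalize=True) * 100.0).round(4).to_dict()
        else:
            shares[col] = {}
    missing = {
        col: int(records[col].isna().sum())
        for col in NUMERIC_COLUMNS + tuple(CATEGORICAL_COLUMNS)
    }
    return SurveySummary(
        n_records=len(records),
        oop_means=oop_means,
        hospitalization_episode_mean=_mean(records[EPISODE_COLUMN]),
        household_income_mean=_mean(records["household_income"]),
        per_capita_income_mean=_mean(records["per_capita_income"]),
        household_annual_oop_mean=_mean(recurring),
        per_capita_annual_oop_mean=_mean(per_capita),
        caregiver_age_mean=_mean(records["caregiver_age"]),
        shares=shares,
        missing_counts=missing,
    )


def rank_categories(summary: SurveySummary) -> list[str]:
    """OOP categories by descending mean annual cost; ties broken alphabetically."""
    present = [(c, m) for c, m in summary.oop_means.items() if m is not None]
    return [c for c, _ in sorted(present, key=lambda cm: (-cm[1], cm[0]))]


def write_summary(summary: SurveySummary, out_dir: str | Path) -> None:
    """Write summary JSON plus a per-category CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "n_records": summary.n_records,
        "oop_means": summary.oop_means,
        "hospitalization_episode_mean": summary.hospitalization_episode_mean,
        "household_income_mean": summary.household_income_mean,
        "per_capita_income_mean": summary.per_capita_income_mean,
        "household_annual_oop_mean": summary.household_annual_oop_mean,
        "per_capita_annual_oop_mean": summary.per_capita_annual_oop_mean,
        "caregiver_age_mean": summary.caregiver_age_mean,
        "shares": summary.shares,
        "missing_counts": summary.missing_counts,
        "category_ranking": rank_categories(summary),
    }
    (out / "survey_summary.json").write_text(json.dumps(payload, indent=2))
    pd.DataFrame(
        {"category": list(summary.oop_means), "mean_annual_usd": list(summary.oop_means.values())}
    ).to_csv(out / "survey_oop_means.csv", index=False)
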