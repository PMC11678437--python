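"""Bundled parameterization of the Colombian child-malnutrition analysis.

Loads the published model inputs shipped with the package: the six-state
transition table and 2021 live-birth cohort, the per-capita direct cost
schedules, the household therapy add-on and poverty lines, the published
per-cycle burden and cost tables (used as calibration targets), and the
caregiver-survey summary statistics.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .burden import BurdenParams, load_burden_config
from .markov import NewbornAllocation, StateSpace, TransitionMatrix, load_model_config

FIXTURE_DIR = Path(__file__).parent / "fixtures"

#: Colombian live births, 2021 (DANE) — the modeled cohort
COHORT_SIZE = 512_611
#: per-capita monthly poverty lines, COP, 2022 (DANE)
EXTREME_POVERTY_LINE_COP = 198_698.0
MONETARY_POVERTY_LINE_COP = 396_864.0

DISABLED_STATES = ("wasting", "stunting", "wasting_stunting")


def model_path() -> Path:
    return FIXTURE_DIR / "colombia_model.yaml"


def burden_path() -> Path:
    return FIXTURE_DIR / "colombia_burden.yaml"


def costs_path() -> Path:
    return FIXTURE_DIR / "colombia_costs.yaml"


def burden_table_path() -> Path:
    return FIXTURE_DIR / "colombia_burden_table.csv"


def cost_table_path() -> Path:
    return FIXTURE_DIR / "colombia_cost_table.csv"


def model() -> tuple[StateSpace, TransitionMatrix, NewbornAllocation, int]:
    """State space, transition matrix (as published), newborn allocation, cycles."""
    return load_model_config(model_path())


def burden_params() -> BurdenParams:
    """Burden conventions with unpublished LE/DW left unset for calibration."""
    return load_burden_config(burden_path())


def cost_config() -> dict:
    from .costs import load_cost_config

    return load_cost_config(costs_path())


def burden_table() -> pd.DataFrame:
    """Published per-cycle YLL/YLD/DALY table, including its Total row."""
    return pd.read_csv(FIXTURE_DIR / "colombia_burden_table.csv")


def cost_table() -> pd.DataFrame:
    """Published per-cycle direct/indirect cost table, including its Total row."""
    return pd.read_csv(FIXTURE_DIR / "colombia_cost_table.csv")


def survey_targets() -> dict:
    """Published caregiver-survey summary statistics (n = 43)."""
    with open(FIXTURE_DIR / "colombia_survey.yaml") as fh:
        return yaml.safe_load(fh)
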