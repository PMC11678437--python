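"""DALY engine: years of life lost (YLL), years lived with disability (YLD).

Per cycle t (annual cycles, t = 1..N):

    YLL_t  = new_deaths_t * (LE - AD_t)
    YLD_t  = sum over disabled states s of occupancy_t(s) * DW(s) * D_t(s)
    DALY_t = YLL_t + YLD_t

with LE the national life expectancy, AD_t the age at death under the
chosen convention (default mid-cycle, AD_t = t - 0.5), DW(s) a disability
weight in [0, 1] and D_t(s) the disability duration (default one year per
prevalent person-cycle).  No discounting or age weighting is applied.

Because disability weights and life expectancy are often cited from GBD
sources without being printed, :func:`calibrate_params` back-solves them
from a target burden table; the calibration model is linear in every free
parameter, so a bounded linear least-squares fit on relative residuals is
exact and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import lsq_linear

from .markov import CohortTrace

__all__ = [
    "BurdenParams",
    "BurdenTable",
    "compute_yll",
    "compute_yld",
    "aggregate_daly",
    "per_1000",
    "calibrate_params",
    "load_burden_config",
]


class BurdenConfigError(ValueError):
    """Missing or inconsistent burden parameterization."""


@dataclass(frozen=True)
class BurdenParams:
    """Life expectancy, disability weights and discretization conventions."""

    life_expectancy: float | None
    disability_weights: Mapping[str, float | None]
    ad_offset: float = 0.5       # AD_t = t - ad_offset (mid-cycle deaths)
    duration_years: float = 1.0  # YLD accrued per prevalent person-cycle

    def __post_init__(self) -> None:
        for s, w in self.disability_weights.items():
            if w is not None and not (0.0 <= w <= 1.0):
                raise BurdenConfigError(f"disability weight for {s!r} outside [0, 1]: {w}")
        if self.life_expectancy is not None and self.life_expectancy <= 0:
            raise BurdenConfigError("life expectancy must be positive")

    def age_at_death(self, cycle: int) -> float:
        return cycle - self.ad_offset

    @property
    def disabled_states(self) -> tuple[str, ...]:
        return tuple(self.disability_weights)


@dataclass(frozen=True)
class BurdenTable:
    """Per-cycle YLL, YLD, DALY and per-1000 normalization (years)."""

    yll: np.ndarray
    yld: np.ndarray
    cohort_size: float

    def __post_init__(self) -> None:
        yll = np.asarray(self.yll, dtype=float)
        yld = np.asarray(self.yld, dtype=float)
        if yll.shape != yld.shape:
            raise ValueError("YLL and YLD series have different lengths")
        if np.any(yll < 0) or np.any(yld < 0):
            raise ValueError("burden entries must be nonnegative")
        object.__setattr__(self, "yll", yll)
        object.__setattr__(self, "yld", yld)

    @property
    def daly(self) -> np.ndarray:
        return self.yll + self.yld

    @property
    def totals(self) -> dict[str, float]:
        """Column sums of the unrounded per-cycle values."""
        return {
            "yll": float(self.yll.sum()),
            "yld": float(self.yld.sum()),
            "daly": float(self.daly.sum()),
            "daly_per_1000": per_1000(float(self.daly.sum()), self.cohort_size),
        }

    def to_frame(self, decimals: int = 2) -> pd.DataFrame:
        """Burden table with a Total row; totals are sums of unrounded values."""
        cycles = np.arange(1, len(self.yll) + 1)
        df = pd.DataFrame(
            {
                "cycle": cycles.astype(object),
                "yll": self.yll,
                "yld": self.yld,
                "daly": self.daly,
                "daly_per_1000": [per_1000(v, self.cohort_size) for v in self.daly],
            }
        )
        tot = self.totals
        df.loc[len(df)] = ["Total", tot["yll"], tot["yld"], tot["daly"], tot["daly_per_1000"]]
        return df.round({"yll": decimals, "yld": decimals, "daly": decimals,
                         "daly_per_1000": decimals})


def compute_yll(trace: CohortTrace, params: BurdenParams) -> np.ndarray:
    """YLL_t = new_deaths_t * (LE - AD_t) for t = 1..N."""
    if params.life_expectancy is None:
        raise BurdenConfigError("life_expectancy is unset (calibrate or supply it)")
    cycles = np.arange(1, trace.n_cycles + 1)
    ad = cycles - params.ad_offset
    lost = params.life_expectancy - ad
    if np.any(lost < 0):
        raise ValueError(
            "age at death exceeds life expectancy under this convention (negative life lost)"
        )
    return trace.new_deaths * lost


def compute_yld(trace: CohortTrace, params: BurdenParams) -> np.ndarray:
    """YLD_t = sum_s occupancy_t(s) * DW(s) * duration, over disabled states."""
    yld = np.zeros(trace.n_cycles)
    for state, weight in params.disability_weights.items():
        occ = trace.state_occupancy(state)[1:]
        if weight is None:
            if np.any(occ > 0):
                raise BurdenConfigError(
                    f"disability weight for occupied state {state!r} is unset"
                )
            continue
        yld += occ * weight * params.duration_years
    return yld


def aggregate_daly(
    yll: Sequence[float], yld: Sequence[float], cohort_size: float
) -> BurdenTable:
    """Combine per-cycle YLL and YLD series into a burden table (DALY = YLL + YLD)."""
    yll = np.asarray(yll, dtype=float)
    yld = np.asarray(yld, dtype=float)
    if yll.shape != yld.shape:
        raise ValueError(f"series lengths differ: {yll.shape} vs {yld.shape}")
    return BurdenTable(yll=yll, yld=yld, cohort_size=cohort_size)


def per_1000(value: float, cohort_size: float) -> float:
    """Normalize a burden (years) per 1000 cohort members, to 2 decimals."""
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    return round(value / cohort_size * 1000.0, 2)


def _relative_residuals(model: np.ndarray, target: np.ndarray) -> np.ndarray:
    scale = np.where(np.abs(target) > 0, np.abs(target), 1.0)
    return (model - target) / scale


def calibrate_params(
    trace: CohortTrace,
    target_yll: Sequence[float],
    target_yld: Sequence[float],
    params: BurdenParams,
    free: Iterable[str] = ("life_expectancy", "disability_weights"),
) -> tuple[BurdenParams, pd.DataFrame]:
    """Back-solve unprinted burden parameters from a target burden table.

    ``free`` may contain ``life_expectancy``, ``ad_offset`` and/or
    ``disability_weights``.  The forward model is linear in each of these,
    so the fit is a bounded linear least squares on relative residuals
    (weights constrained to [0, 1]); it is deterministic and globally
    optimal.  Returns the fitted parameters and a per-cell residual report.
    """
    free = set(free)
    known = {"life_expectancy", "ad_offset", "disability_weights"}
    if free - known:
        raise ValueError(f"unknown free parameters: {sorted(free - known)}")
    target_yll = np.asarray(target_yll, dtype=float)
    target_yld = np.asarray(target_yld, dtype=float)
    n = trace.n_cycles
    if len(target_yll) != n or len(target_yld) != n:
        raise ValueError("target table length does not match trace cycles")
    fitted = params

    # --- mortality side: YLL_t = deaths_t * (LE - t + offset), linear in (LE, offset)
    mort_free = [p for p in ("life_expectancy", "ad_offset") if p in free]
    if mort_free:
        deaths = trace.new_deaths
        cycles = np.arange(1, n + 1)
        # identifiability comes from the design: a cycle with zero deaths
        # carries no information about LE or the death-age offset
        cells = int(np.count_nonzero(deaths))
        if cells < len(mort_free):
            raise BurdenConfigError(
                f"underdetermined mortality calibration: {cells} cycles with deaths "
                f"for free parameters {mort_free}"
            )
        scale = np.where(np.abs(target_yll) > 0, np.abs(target_yll), 1.0)
        cols = []
        if "life_expectancy" in free:
            cols.append(deaths / scale)
        if "ad_offset" in free:
            cols.append(deaths / scale)
        A = np.column_stack(cols)
        # target = deaths*LE + deaths*offset - deaths*t, so move known terms right
        b = (target_yll + deaths * cycles) / scale
        if "life_expectancy" not in free:
            if params.life_expectancy is None:
                raise BurdenConfigError("life_expectancy fixed but unset")
            b = b - (deaths * params.life_expectancy) / scale
        if "ad_offset" not in free:
            b = b - (deaths * params.ad_offset) / scale
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        i = 0
        if "life_expectancy" in free:
            fitted = replace(fitted, life_expectancy=float(sol[i])); i += 1
        if "ad_offset" in free:
            fitted = replace(fitted, ad_offset=float(sol[i]))

    # --- disability side: YLD_t = sum_s occ_t(s) * DW_s, linear in DW, 0 <= DW <= 1
    if "disability_weights" in free:
        states = list(params.disability_weights)
        occ = np.column_stack([trace.state_occupancy(s)[1:] for s in states])
        occ = occ * params.duration_years
        rank = np.linalg.matrix_rank(occ)
        if rank < len(states):
            raise BurdenConfigError(
                f"underdetermined disability calibration: occupancy design has rank "
                f"{rank} for weights {states}"
            )
        scale = np.where(np.abs(target_yld) > 0, np.abs(target_yld), 1.0)
        res = lsq_linear(occ / scale[:, None], target_yld / scale, bounds=(0.0, 1.0))
        fitted = replace(
            fitted,
            disability_weights={s: float(w) for s, w in zip(states, res.x)},
        )

    # raw model values for the residual report (no nonnegativity guard: a
    # fit against inconsistent targets may imply LE < AD, and the report
    # must show that honestly)
    cycles = np.arange(1, n + 1)
    model_yll = trace.new_deaths * (fitted.life_expectancy - (cycles - fitted.ad_offset))
    model_yld = compute_yld(trace, fitted)
    report = pd.DataFrame(
        {
            "cycle": np.arange(1, n + 1),
            "target_yll": target_yll,
            "model_yll": model_yll,
            "rel_resid_yll": _relative_residuals(model_yll, target_yll),
            "target_yld": target_yld,
            "model_yld": model_yld,
            "rel_resid_yld": _relative_residuals(model_yld, target_yld),
        }
    )
    return fitted, report


def load_burden_config(path: str | Path) -> BurdenParams:
    """Read a burden config (LE, DW map, convention selectors)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    conventions = {"mid_cycle": 0.5, "cycle_end": 0.0, "cycle_start": 1.0}
    ad = cfg.get("age_at_death_convention", "mid_cycle")
    if ad not in conventions:
        raise BurdenConfigError(f"unknown age_at_death_convention {ad!r}")
    le = cfg.get("life_expectancy")
    return BurdenParams(
        life_expectancy=None if le is None else float(le),
        disability_weights={
            k: (None if v is None else float(v))
            for k, v in cfg.get("disability_weights", {}).items()
        },
        ad_offset=conventions[ad],
    )
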