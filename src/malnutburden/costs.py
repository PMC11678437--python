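"""Cost-of-illness engine: direct (health-system) and indirect (household) costs.

Costs accrue per person-cycle of end-of-cycle state occupancy (prevalence
costing).  A state's direct unit cost is either a single amount or a
weighted composition of component costs (e.g. respiratory and diarrheal
episodes for the wasting state), or the maximum over other states'
costs; a payer split says what fraction the health system bears.  Costs
carry a price year and are standardized to a target year with
configurable inflation factors.  Indirect costs add per-person household
out-of-pocket amounts plus a fixed annual therapy add-on for stunted
children active only from a configured cycle (age two onward by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .markov import CohortTrace

__all__ = [
    "UnitCost",
    "CostComponent",
    "StateCostSchedule",
    "InflationSeries",
    "CostTable",
    "TherapyAddon",
    "inflate",
    "blended_state_cost",
    "resolve_schedules",
    "accrue_direct",
    "accrue_indirect",
    "totals_and_shares",
    "poverty_burden_ratio",
    "back_solve_indirect",
    "load_cost_config",
]


class CostConfigError(ValueError):
    """Missing factor, unknown state, or inconsistent cost configuration."""


@dataclass(frozen=True)
class UnitCost:
    amount: float
    price_year: int
    description: str = ""

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("unit cost amount must be nonnegative")


@dataclass(frozen=True)
class CostComponent:
    weight: float
    cost: UnitCost

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("composition weight must be nonnegative")


@dataclass(frozen=True)
class StateCostSchedule:
    """Per-state direct cost: composition OR a max-of rule over other states.

    Composition weights are used exactly as configured and are NOT
    renormalized (incidence-style weights may deliberately sum to less
    than 1).  ``payer_split`` fractions must sum to 1.
    """

    state: str
    components: tuple[CostComponent, ...] = ()
    max_of: tuple[str, ...] = ()
    payer_split: Mapping[str, float] = None  # type: ignore[assignment]
    active_cycles: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.payer_split is None:
            object.__setattr__(self, "payer_split", {"system": 1.0, "household": 0.0})
        total = sum(self.payer_split.values())
        if abs(total - 1.0) > 1e-9:
            raise CostConfigError(f"payer split for {self.state!r} sums to {total}, not 1")
        if bool(self.components) == bool(self.max_of):
            raise CostConfigError(
                f"schedule for {self.state!r} needs components or a max_of rule, not both"
            )


@dataclass(frozen=True)
class InflationSeries:
    """Multiplicative factors keyed by (from_year, to_year); identity on equal years."""

    factors: Mapping[tuple[int, int], float]

    def __post_init__(self) -> None:
        for (y1, y2), f in self.factors.items():
            if f <= 0:
                raise ValueError(f"inflation factor {y1}->{y2} must be positive")
            if y1 == y2 and abs(f - 1.0) > 1e-12:
                raise ValueError(f"factor({y1}, {y1}) must be 1")

    def factor(self, from_year: int, to_year: int) -> float:
        if from_year == to_year:
            return 1.0
        try:
            return self.factors[(from_year, to_year)]
        except KeyError:
            raise CostConfigError(
                f"no inflation factor configured for {from_year} -> {to_year}"
            ) from None


def inflate(cost: UnitCost, series: InflationSeries, to_year: int) -> UnitCost:
    """Standardize a unit cost to ``to_year`` prices."""
    f = series.factor(cost.price_year, to_year)
    return replace(cost, amount=cost.amount * f, price_year=to_year)


def blended_state_cost(schedule: StateCostSchedule) -> float:
    """Weighted sum of component amounts (components must share a price year)."""
    if not schedule.components:
        raise CostConfigError(f"schedule for {schedule.state!r} has no components to blend")
    years = {c.cost.price_year for c in schedule.components}
    if len(years) > 1:
        raise CostConfigError(
            f"components of {schedule.state!r} span price years {sorted(years)}; inflate first"
        )
    return sum(c.weight * c.cost.amount for c in schedule.components)


def resolve_schedules(
    schedules: Iterable[StateCostSchedule],
    series: InflationSeries,
    target_year: int,
) -> dict[str, tuple[StateCostSchedule, float]]:
    """Inflate all components to the target year and resolve per-state amounts.

    A max-of rule resolves after its referenced states and takes the
    maximum over every individual cost item they carry (a combined state
    assumed "equal to the maximum cost between the previous items" picks
    the dearest single item, not a blended average).  Returns
    ``{state: (inflated schedule, per-person-cycle amount)}``.
    """
    pending = {s.state: s for s in schedules}
    resolved: dict[str, tuple[StateCostSchedule, float]] = {}
    while pending:
        progressed = False
        for state in list(pending):
            sched = pending[state]
            if sched.max_of:
                if not set(sched.max_of) <= set(resolved):
                    continue
                items: list[float] = []
                for ref in sched.max_of:
                    ref_sched, ref_amount = resolved[ref]
                    if ref_sched.components:
                        items.extend(c.cost.amount for c in ref_sched.components)
                    else:
                        items.append(ref_amount)
                amount = max(items)
                resolved[state] = (sched, amount)
            else:
                infl = replace(
                    sched,
                    components=tuple(
                        replace(c, cost=inflate(c.cost, series, target_year))
                        for c in sched.components
                    ),
                )
                resolved[state] = (infl, blended_state_cost(infl))
            del pending[state]
            progressed = True
        if not progressed:
            raise CostConfigError(
                f"unresolvable max_of references among schedules: {sorted(pending)}"
            )
    return resolved


def accrue_direct(
    trace: CohortTrace,
    resolved: Mapping[str, tuple[StateCostSchedule, float]],
) -> np.ndarray:
    """Per-cycle health-system cost: occupancy x system share x unit cost.

    Each state's cost accrues only in its configured active cycles (e.g.
    occupational therapy for stunting only from age two).
    """
    unknown = set(resolved) - set(trace.space.names)
    if unknown:
        raise CostConfigError(f"cost schedule references unknown states: {sorted(unknown)}")
    direct = np.zeros(trace.n_cycles)
    for state, (sched, amount) in resolved.items():
        occ = trace.state_occupancy(state)[1:]
        share = sched.payer_split.get("system", 0.0)
        for t in range(1, trace.n_cycles + 1):
            if t in sched.active_cycles:
                direct[t - 1] += occ[t - 1] * share * amount
    return direct


@dataclass(frozen=True)
class TherapyAddon:
    """Fixed annual household therapy cost for stunted children."""

    amount: float = 920.0
    states: tuple[str, ...] = ("stunting", "wasting_stunting")
    active_cycles: frozenset[int] = frozenset({3, 4})


def accrue_indirect(
    trace: CohortTrace,
    household_costs: Mapping[str, float],
    addon: TherapyAddon | None = None,
) -> np.ndarray:
    """Per-cycle household cost: per-person OOP plus the therapy add-on.

    ``household_costs`` maps state -> per-person annual household cost
    (out-of-pocket spending and productivity losses).  The therapy add-on
    accrues per stunted person-cycle only in its active cycles.
    """
    unknown = set(household_costs) - set(trace.space.names)
    if unknown:
        raise CostConfigError(f"household costs reference unknown states: {sorted(unknown)}")
    if any(v < 0 for v in household_costs.values()):
        raise ValueError("household costs must be nonnegative")
    indirect = np.zeros(trace.n_cycles)
    for state, per_person in household_costs.items():
        indirect += trace.state_occupancy(state)[1:] * per_person
    if addon is not None:
        for state in addon.states:
            occ = trace.state_occupancy(state)[1:]
            for t in range(1, trace.n_cycles + 1):
                if t in addon.active_cycles:
                    indirect[t - 1] += occ[t - 1] * addon.amount
    return indirect


@dataclass(frozen=True)
class CostTable:
    """Per-cycle direct and indirect accruals with totals and payer shares."""

    direct: np.ndarray
    indirect: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direct, dtype=float)
        i = np.asarray(self.indirect, dtype=float)
        if d.shape != i.shape:
            raise ValueError("direct and indirect series have different lengths")
        object.__setattr__(self, "direct", d)
        object.__setattr__(self, "indirect", i)

    def to_frame(self, decimals: int = 2) -> pd.DataFrame:
        cycles = np.arange(1, len(self.direct) + 1)
        df = pd.DataFrame(
            {"cycle": cycles.astype(object), "direct": self.direct, "indirect": self.indirect}
        )
        df.loc[len(df)] = ["Total", self.direct.sum(), self.indirect.sum()]
        return df.round({"direct": decimals, "indirect": decimals})


def totals_and_shares(table: CostTable) -> dict[str, float]:
    """Column totals, grand total, and integer percentage shares by payer."""
    total_direct = float(table.direct.sum())
    total_indirect = float(table.indirect.sum())
    grand = total_direct + total_indirect
    share_direct = total_direct / grand * 100.0 if grand > 0 else 0.0
    share_indirect = total_indirect / grand * 100.0 if grand > 0 else 0.0
    return {
        "total_direct": total_direct,
        "total_indirect": total_indirect,
        "grand_total": grand,
        "share_direct_pct": share_direct,
        "share_indirect_pct": share_indirect,
        "share_direct_pct_rounded": round(share_direct),
        "share_indirect_pct_rounded": round(share_indirect),
    }


def poverty_burden_ratio(
    annual_oop: float, monthly_poverty_line: float, months: int = 12
) -> float:
    """Annual out-of-pocket spending as % of annual income at a poverty line."""
    if monthly_poverty_line <= 0:
        raise ValueError("poverty line must be positive")
    if annual_oop < 0:
        raise ValueError("annual out-of-pocket spending must be nonnegative")
    return annual_oop / (monthly_poverty_line * months) * 100.0


def back_solve_indirect(
    trace: CohortTrace,
    target_indirect: Sequence[float],
    states: Sequence[str],
    addon: TherapyAddon | None = None,
) -> pd.DataFrame:
    """Target mode: implied per-person household cost per cycle.

    Given a published per-cycle indirect-cost column, subtract the therapy
    add-on and divide by the occupancy of the costed states, yielding the
    per-person annual household amount each cycle implies.  These
    back-solved values are reported for audit, mirroring the burden
    calibration (exact forward reproduction is not claimed when the
    per-person inputs were never published).
    """
    target = np.asarray(target_indirect, dtype=float)
    if len(target) != trace.n_cycles:
        raise ValueError("target indirect series does not match trace cycles")
    occ = np.sum([trace.state_occupancy(s)[1:] for s in states], axis=0)
    addon_part = np.zeros(trace.n_cycles)
    if addon is not None:
        for state in addon.states:
            socc = trace.state_occupancy(state)[1:]
            for t in range(1, trace.n_cycles + 1):
                if t in addon.active_cycles:
                    addon_part[t - 1] += socc[t - 1] * addon.amount
    residual = target - addon_part
    with np.errstate(divide="ignore", invalid="ignore"):
        implied = np.where(occ > 0, residual / occ, np.nan)
    return pd.DataFrame(
        {
            "cycle": np.arange(1, trace.n_cycles + 1),
            "target_indirect": target,
            "therapy_addon": addon_part,
            "costed_occupancy": occ,
            "implied_per_person": implied,
        }
    )


def load_cost_config(path: str | Path) -> dict:
    """Read a cost config: schedules, inflation factors, add-on, poverty lines.

    Returns a dict with keys ``schedules`` (list of StateCostSchedule),
    ``inflation`` (InflationSeries), ``target_year``, ``household_costs``,
    ``addon`` (TherapyAddon) and ``poverty`` (raw mapping).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    series = InflationSeries(
        {
            (int(e["from_year"]), int(e["to_year"])): float(e["factor"])
            for e in cfg.get("inflation_factors", [])
        }
    )
    schedules = []
    for state, raw in cfg.get("schedules", {}).items():
        schedules.append(
            StateCostSchedule(
                state=state,
                components=tuple(
                    CostComponent(
                        weight=float(c["weight"]),
                        cost=UnitCost(
                            amount=float(c["amount"]),
                            price_year=int(c["price_year"]),
                            description=c.get("description", ""),
                        ),
                    )
                    for c in raw.get("components", [])
                ),
                max_of=tuple(raw.get("max_of", ())),
                payer_split=raw.get("payer_split"),
                active_cycles=frozenset(int(t) for t in raw.get("active_cycles", [])),
            )
        )
    ind = cfg.get("indirect", {})
    addon_cfg = ind.get("therapy_addon")
    addon = None
    if addon_cfg:
        addon = TherapyAddon(
            amount=float(addon_cfg["amount"]),
            states=tuple(addon_cfg.get("states", ("stunting", "wasting_stunting"))),
            active_cycles=frozenset(int(t) for t in addon_cfg.get("active_cycles", (3, 4))),
        )
    return {
        "schedules": schedules,
        "inflation": series,
        "target_year": int(cfg.get("target_year", 2023)),
        "household_costs": {
            k: float(v) for k, v in (ind.get("household_costs") or {}).items()
        },
        "addon": addon,
        "poverty": cfg.get("poverty", {}),
    }
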