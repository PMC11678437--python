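"""Discrete-time Markov cohort engine.

A closed cohort is propagated through annual cycles by repeated
multiplication of the occupancy vector with a row-stochastic transition
matrix, ``M^(n+1) = M^n P``.  States are mutually exclusive and exhaustive;
death is absorbing.  Newborns enter through a one-shot allocation row that
is not itself a persistent state.  Fractional persons are carried exactly;
rounding happens only at reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StateSpace",
    "TransitionMatrix",
    "NewbornAllocation",
    "CohortTrace",
    "ValidationReport",
    "validate_matrix",
    "allocate_newborns",
    "step",
    "simulate",
    "occupancy_by_power",
    "load_model_config",
]

#: relative tolerance for cohort mass conservation checks
MASS_RTOL = 1e-6


class ModelStructureError(ValueError):
    """Raised when model components are dimensionally or structurally inconsistent."""


@dataclass(frozen=True)
class StateSpace:
    """Ordered persistent health states, with a subset flagged absorbing.

    ``newborn_row_label`` names the one-shot allocation row (e.g. the
    newborn row of a published transition table); it is *not* a member of
    the persistent state set used in occupancy vectors.
    """

    names: tuple[str, ...]
    absorbing: frozenset[str] = frozenset()
    newborn_row_label: str = "newborn"

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise ModelStructureError("a state space needs at least 2 states")
        if len(set(self.names)) != len(self.names):
            raise ModelStructureError("state names must be unique")
        unknown = set(self.absorbing) - set(self.names)
        if unknown:
            raise ModelStructureError(f"absorbing states not in state space: {sorted(unknown)}")
        if self.newborn_row_label in self.names:
            raise ModelStructureError(
                "the newborn allocation row must not be a persistent state"
            )

    @property
    def k(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown state {name!r}") from None

    @property
    def absorbing_indices(self) -> tuple[int, ...]:
        return tuple(i for i, s in enumerate(self.names) if s in self.absorbing)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition matrix P = (p_ij) over a state space.

    Row i is the one-cycle distribution over next states given current
    state i.  The matrix is time-homogeneous.  ``row_tolerance`` is the
    largest row-sum deviation from 1 accepted (and repaired by
    renormalization); published matrices rounded to 4 decimals typically
    need about 1e-3.
    """

    entries: np.ndarray
    row_tolerance: float = 1e-3

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        if entries.ndim != 2 or entries.shape[0] != entries.shape[1]:
            raise ModelStructureError(f"transition matrix must be square, got {entries.shape}")
        object.__setattr__(self, "entries", entries)
        if self.row_tolerance < 0:
            raise ValueError("row_tolerance must be nonnegative")

    @property
    def k(self) -> int:
        return self.entries.shape[0]

    def renormalized(self) -> "TransitionMatrix":
        """Divide each row by its sum so rows sum to 1 within 1e-12."""
        sums = self.entries.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError("cannot renormalize a row with nonpositive sum")
        return TransitionMatrix(self.entries / sums, self.row_tolerance)


@dataclass(frozen=True)
class NewbornAllocation:
    """Initial cohort size and its split over starting states."""

    cohort_size: float
    split: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.cohort_size <= 0:
            raise ValueError("cohort_size must be positive")
        if any(v < 0 for v in self.split.values()):
            raise ValueError("split probabilities must be nonnegative")


@dataclass(frozen=True)
class RowDiagnostic:
    state: str
    row_sum: float
    status: str  # "pass" | "warn" | "fail"
    message: str = ""


@dataclass(frozen=True)
class ValidationReport:
    status: str  # "pass" | "warn" | "fail"
    rows: tuple[RowDiagnostic, ...]
    renormalized: TransitionMatrix | None = None

    @property
    def ok(self) -> bool:
        return self.status != "fail"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"matrix validation: {self.status}"]
        lines += [f"  {r.state}: sum={r.row_sum:.6f} [{r.status}] {r.message}" for r in self.rows]
        return "\n".join(lines)


def validate_matrix(
    matrix: TransitionMatrix,
    space: StateSpace,
    renormalize: bool = True,
) -> ValidationReport:
    """Check entry ranges, row-stochasticity and absorbing structure.

    Entries outside [0, 1] or row sums deviating from 1 by more than
    ``row_tolerance`` fail; smaller deviations warn and (by default) are
    repaired by dividing the row by its sum.  A state flagged absorbing
    must be an exact unit self-loop.
    """
    P = matrix.entries
    if P.shape[0] != space.k:
        raise ModelStructureError(
            f"matrix is {P.shape[0]}x{P.shape[1]} but state space has {space.k} states"
        )
    diagnostics: list[RowDiagnostic] = []
    status = "pass"
    for i, name in enumerate(space.names):
        row = P[i]
        row_sum = float(row.sum())
        if np.any(row < 0) or np.any(row > 1):
            diagnostics.append(RowDiagnostic(name, row_sum, "fail", "entry outside [0, 1]"))
            status = "fail"
            continue
        if name in space.absorbing:
            if not (row[i] == 1.0 and row_sum == 1.0):
                diagnostics.append(
                    RowDiagnostic(name, row_sum, "fail", "absorbing row is not a unit self-loop")
                )
                status = "fail"
                continue
        dev = abs(row_sum - 1.0)
        if dev > matrix.row_tolerance:
            diagnostics.append(
                RowDiagnostic(name, row_sum, "fail", f"row sum off by {dev:.2e} > tolerance")
            )
            status = "fail"
        elif dev > 1e-12:
            diagnostics.append(
                RowDiagnostic(name, row_sum, "warn", "row sum repaired by renormalization")
            )
            if status == "pass":
                status = "warn"
        else:
            diagnostics.append(RowDiagnostic(name, row_sum, "pass"))
    repaired = None
    if status != "fail" and renormalize:
        repaired = matrix.renormalized()
    return ValidationReport(status, tuple(diagnostics), repaired)


def allocate_newborns(alloc: NewbornAllocation, space: StateSpace) -> np.ndarray:
    """Spread the cohort over initial states: M^0_j = cohort_size * split_j.

    Mass on an absorbing state (a newborn allocated directly to death) is
    rejected.
    """
    split = np.zeros(space.k)
    for name, p in alloc.split.items():
        j = space.index(name)
        if name in space.absorbing and p > 0:
            raise ValueError(f"newborn split places mass on absorbing state {name!r}")
        split[j] = p
    total = split.sum()
    if abs(total - 1.0) > 1e-3:
        raise ValueError(f"newborn split sums to {total:.6f}, not 1")
    split /= total
    return alloc.cohort_size * split


def step(occupancy: np.ndarray, matrix: TransitionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """One cycle: returns (M P, flow matrix) with flow_(i,j) = M_i p_ij."""
    occupancy = np.asarray(occupancy, dtype=float)
    if occupancy.ndim != 1 or occupancy.size != matrix.k:
        raise ModelStructureError("occupancy vector does not match matrix dimension")
    if np.any(occupancy < 0):
        raise ValueError("occupancy must be nonnegative")
    flows = occupancy[:, None] * matrix.entries
    return flows.sum(axis=0), flows


@dataclass
class CohortTrace:
    """Occupancy and flow record of a simulated cohort.

    ``occupancy[n]`` is M^n (persons per state, fractional persons allowed)
    for n = 0..N; ``flows[t-1]`` holds persons moving i -> j during cycle t;
    ``new_deaths[t-1]`` is the mass entering absorbing states in cycle t.
    """

    space: StateSpace
    occupancy: np.ndarray          # (N+1, k)
    flows: np.ndarray              # (N, k, k)
    new_deaths: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        self.flows = np.asarray(self.flows, dtype=float)
        if self.new_deaths is None:
            dead = self.occupancy[:, list(self.space.absorbing_indices)].sum(axis=1)
            self.new_deaths = np.diff(dead)
        else:
            self.new_deaths = np.asarray(self.new_deaths, dtype=float)
        self.validate()

    def validate(self) -> None:
        if np.any(self.occupancy < -1e-9):
            raise ValueError("negative occupancy in trace")
        totals = self.occupancy.sum(axis=1)
        if not np.allclose(totals, totals[0], rtol=MASS_RTOL):
            raise ValueError("cohort mass not conserved across cycles")
        dead = self.occupancy[:, list(self.space.absorbing_indices)].sum(axis=1)
        if np.any(np.diff(dead) < -1e-9 * max(totals[0], 1.0)):
            raise ValueError("cumulative deaths decreased")

    @property
    def cohort_size(self) -> float:
        return float(self.occupancy[0].sum())

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def state_occupancy(self, name: str) -> np.ndarray:
        """Occupancy series for one state, n = 0..N."""
        return self.occupancy[:, self.space.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (cycle, state, occupancy) table."""
        recs = [
            {"cycle": n, "state": s, "occupancy": self.occupancy[n, j]}
            for n in range(self.occupancy.shape[0])
            for j, s in enumerate(self.space.names)
        ]
        return pd.DataFrame.from_records(recs)

    def flows_frame(self) -> pd.DataFrame:
        """Tidy (cycle, from_state, to_state, flow) table; cycle t covers n-1 -> n."""
        recs = [
            {"cycle": t + 1, "from_state": a, "to_state": b, "flow": self.flows[t, i, j]}
            for t in range(self.flows.shape[0])
            for i, a in enumerate(self.space.names)
            for j, b in enumerate(self.space.names)
        ]
        return pd.DataFrame.from_records(recs)


def simulate(
    alloc: NewbornAllocation,
    matrix: TransitionMatrix,
    space: StateSpace,
    n_cycles: int,
    validate: bool = True,
) -> CohortTrace:
    """Propagate the cohort for ``n_cycles`` annual cycles.

    The matrix is validated (and rows renormalized) unless ``validate`` is
    False, in which case entries are used exactly as given.
    """
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    if validate:
        report = validate_matrix(matrix, space, renormalize=True)
        if not report.ok:
            raise ValueError(f"invalid transition matrix:\n{report}")
        matrix = report.renormalized or matrix
    m = allocate_newborns(alloc, space)
    occupancy = [m]
    flows = []
    for _ in range(n_cycles):
        m, f = step(m, matrix)
        occupancy.append(m)
        flows.append(f)
    return CohortTrace(
        space,
        np.vstack(occupancy),
        np.stack(flows) if flows else np.zeros((0, space.k, space.k)),
    )


def occupancy_by_power(
    alloc: NewbornAllocation,
    matrix: TransitionMatrix,
    space: StateSpace,
    n: int,
) -> np.ndarray:
    """M^0 P^n by explicit matrix exponentiation (oracle for ``simulate``)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    m0 = allocate_newborns(alloc, space)
    return m0 @ np.linalg.matrix_power(matrix.entries, n)


def load_model_config(
    path: str | Path,
) -> tuple[StateSpace, TransitionMatrix, NewbornAllocation, int]:
    """Read a model definition file (states, matrix, newborn split, cycles)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    names = tuple(cfg["states"])
    space = StateSpace(
        names=names,
        absorbing=frozenset(cfg.get("absorbing", ())),
        newborn_row_label=cfg.get("newborn_row_label", "newborn"),
    )
    tol = float(cfg.get("row_tolerance", 1e-3))
    rows = cfg["transitions"]
    missing = set(names) - set(rows)
    if missing:
        raise ModelStructureError(f"transitions missing for states: {sorted(missing)}")
    P = np.array([[float(rows[a].get(b, 0.0)) for b in names] for a in names])
    matrix = TransitionMatrix(P, row_tolerance=tol)
    alloc = NewbornAllocation(
        cohort_size=float(cfg["cohort_size"]),
        split={k: float(v) for k, v in cfg["newborn_split"].items()},
    )
    return space, matrix, alloc, int(cfg.get("n_cycles", 4))
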