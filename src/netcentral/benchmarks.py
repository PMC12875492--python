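"""Numerical battery: measure trajectories over canonical graph families.

Each of the six deterministic families encodes an expected limiting
behavior as the order n grows:

- star: maximal centralization, value exactly 1 at every n;
- ring, complete: no distinct node, value exactly 0 at every n;
- perturbed star (one edge rewired): nearly maximal, value should approach
  1 as the perturbation becomes negligible;
- perturbed ring (one edge rewired), perturbed complete (one edge removed):
  a slight, nonzero centralization at small n that should vanish as n grows.

The verdicts discretize those expectations: exact criteria use the
per-measure boundary tolerances; "approach one" requires the value at the
largest grid point to reach ``theta_high`` (default 0.9); "approach zero"
requires a detectable (above-tolerance) response at the smallest grid point
and a final value at or below ``theta_low`` (default 0.05).  With the
default grid {5, 10, 20, 50, 100, 200} these cutoffs sit well clear of the
asymptotics of every measure/family pair (the closest calls: NNC on the
perturbed star reaches ~0.95 at n=200, decaying measures on the perturbed
ring sit at ~0.02 or below, while the failing measures plateau at 0.43+).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .graph_core import FAMILIES, make_family
from .measures import MEASURE_IDS, TOLERANCES, measure_all

__all__ = [
    "DEFAULT_GRID",
    "FAMILY_CRITERIA",
    "BenchmarkVerdictMatrix",
    "Trajectory",
    "TrajectoryCriterion",
    "evaluate_criterion",
    "run_numerical_battery",
    "trajectory",
]

DEFAULT_GRID: tuple[int, ...] = (5, 10, 20, 50, 100, 200)

FAMILY_ORDER = (
    "star",
    "ring",
    "complete",
    "perturbed_star",
    "perturbed_ring",
    "perturbed_complete",
)


@dataclass(frozen=True)
class TrajectoryCriterion:
    """Pass rule for one family's value trajectory."""

    kind: str  # exact-one | exact-zero | approach-one | approach-zero
    theta_high: float = 0.9
    theta_low: float = 0.05

    def __post_init__(self):
        if self.kind not in ("exact-one", "exact-zero", "approach-one", "approach-zero"):
            raise ValueError(f"unknown criterion kind {self.kind!r}")
        if not 0.0 < self.theta_low < self.theta_high < 1.0:
            raise ValueError("need 0 < theta_low < theta_high < 1")


#: family -> expected-behavior criterion
FAMILY_CRITERIA: dict[str, str] = {
    "star": "exact-one",
    "ring": "exact-zero",
    "complete": "exact-zero",
    "perturbed_star": "approach-one",
    "perturbed_ring": "approach-zero",
    "perturbed_complete": "approach-zero",
}


@dataclass(frozen=True)
class Trajectory:
    measure: str
    family: str
    grid: tuple[int, ...]
    values: tuple[float, ...]


@dataclass
class BenchmarkVerdictMatrix:
    """measures x families pass/fail grid with the underlying trajectories."""

    passed: dict[tuple[str, str], bool]
    trajectories: dict[tuple[str, str], Trajectory]
    measures: tuple[str, ...]
    families: tuple[str, ...] = FAMILY_ORDER

    @property
    def passed_counts(self) -> dict[str, int]:
        return {
            m: sum(self.passed[(m, f)] for f in self.families) for m in self.measures
        }

    def to_dataframe(self):
        import pandas as pd

        rows = {}
        for m in self.measures:
            row = {f: ("✓" if self.passed[(m, f)] else "✗") for f in self.families}
            row["# Passed"] = self.passed_counts[m]
            rows[m] = row
        return pd.DataFrame.from_dict(rows, orient="index")

    def to_json_dict(self) -> dict:
        return {
            "families": list(self.families),
            "passed_counts": self.passed_counts,
            "cells": [
                {
                    "measure": m,
                    "family": f,
                    "passed": self.passed[(m, f)],
                    "grid": list(self.trajectories[(m, f)].grid),
                    "values": list(self.trajectories[(m, f)].values),
                }
                for m in self.measures
                for f in self.families
            ],
        }


def trajectory(
    measure: str, family: str, grid: tuple[int, ...] = DEFAULT_GRID
) -> Trajectory:
    """Evaluate ``measure`` on ``family`` graphs over the order grid."""
    _, min_n = FAMILIES[family]
    bad = [n for n in grid if n < min_n]
    if bad:
        raise ValueError(f"grid points {bad} below minimum order {min_n} for {family}")
    values = tuple(
        measure_all(make_family(family, n), (measure,))[measure].value for n in grid
    )
    return Trajectory(measure, family, tuple(grid), values)


def evaluate_criterion(t: Trajectory, c: TrajectoryCriterion) -> bool:
    """Apply a criterion to a trajectory; see the module docstring."""
    if not t.values:
        raise ValueError("empty trajectory")
    tol = TOLERANCES[t.measure]
    if c.kind == "exact-one":
        return all(abs(v - 1.0) <= tol for v in t.values)
    if c.kind == "exact-zero":
        return all(abs(v) <= tol for v in t.values)
    if c.kind == "approach-one":
        return t.values[-1] >= c.theta_high
    # approach-zero: a detectable response at the smallest order that vanishes
    return t.values[0] > tol and t.values[-1] <= c.theta_low


def run_numerical_battery(
    measure_ids: tuple[str, ...] | None = None,
    grid: tuple[int, ...] = DEFAULT_GRID,
    *,
    theta_high: float = 0.9,
    theta_low: float = 0.05,
) -> BenchmarkVerdictMatrix:
    """Evaluate every measure on every family and apply the family criteria.

    Graphs are generated once per (family, order) and all measures are read
    off the same graph.
    """
    ids = tuple(measure_ids) if measure_ids is not None else MEASURE_IDS
    values: dict[tuple[str, str], list[float]] = {
        (m, f): [] for m in ids for f in FAMILY_ORDER
    }
    for f in FAMILY_ORDER:
        for n in grid:
            vals = measure_all(make_family(f, n), ids)
            for m in ids:
                values[(m, f)].append(vals[m].value)
    trajectories = {
        (m, f): Trajectory(m, f, tuple(grid), tuple(v))
        for (m, f), v in values.items()
    }
    passed = {
        key: evaluate_criterion(
            traj,
            TrajectoryCriterion(
                FAMILY_CRITERIA[key[1]], theta_high=theta_high, theta_low=theta_low
            ),
        )
        for key, traj in trajectories.items()
    }
    return BenchmarkVerdictMatrix(passed, trajectories, ids)
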