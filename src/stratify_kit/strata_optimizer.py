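"""Cost-optimal thresholds between risk-stratified management levels.

Patients are ranked by predicted risk and split into equal-count
percentile bins (bin 1 = highest risk). Enrolling an average patient of a
bin into a management program changes expected future cost by

    delta = c_i - avg_n_e * p * c_e

where c_i is the program's cost per patient, p the fraction of
undesirable events it avoids, avg_n_e the bin's mean event count and c_e
the mean cost of one event. Proceeding from the highest-risk bin down,
each bin gets the remaining-capacity level with the smallest delta; a
zero-cost zero-benefit "no program" level keeps the problem feasible and
anchors delta = 0 as the no-enrollment comparator. Thresholds between
strata are the bin boundaries where the chosen level changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

NULL_LEVEL_NAME = "none"


@dataclass(frozen=True)
class ManagementLevel:
    """A program in the management hierarchy.

    ``capacity`` is a maximum enrollable patient count (None = unbounded).
    """

    name: str
    c_i: float  # average program cost per patient per period
    p: float  # fraction of undesirable events the program avoids
    capacity: float | None = None

    def __post_init__(self):
        if self.c_i < 0:
            raise ValueError("c_i must be nonnegative")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.capacity is not None and self.capacity < 0:
            raise ValueError("capacity must be nonnegative")


NULL_LEVEL = ManagementLevel(NULL_LEVEL_NAME, 0.0, 0.0, None)


@dataclass
class PercentileStats:
    """Per-bin event statistics; bin 1 holds the highest predicted risk."""

    avg_n_e: np.ndarray  # mean undesirable events per patient, by bin
    n_patients: np.ndarray  # patients per bin
    c_e: float  # average cost of one undesirable event

    def __post_init__(self):
        self.avg_n_e = np.asarray(self.avg_n_e, dtype=float)
        self.n_patients = np.asarray(self.n_patients, dtype=int)
        if (self.avg_n_e < 0).any():
            raise ValueError("avg_n_e must be nonnegative")
        if len(self.avg_n_e) != len(self.n_patients):
            raise ValueError("avg_n_e and n_patients must align")

    @property
    def n_bins(self) -> int:
        return len(self.avg_n_e)


@dataclass
class StratificationPolicy:
    """Assignment of management levels to risk-percentile bins."""

    assignments: list[str]  # level name per bin, bin 1 first
    deltas: np.ndarray  # expected per-patient cost change per bin
    n_patients: np.ndarray
    levels: dict[str, ManagementLevel]
    #: bin indices (1-based) at which the assigned level changes
    thresholds: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.thresholds = [
            b + 1
            for b in range(1, len(self.assignments))
            if self.assignments[b] != self.assignments[b - 1]
        ]

    @property
    def total_expected_delta(self) -> float:
        return float(np.sum(self.deltas * self.n_patients))

    def enrollment_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for name, n in zip(self.assignments, self.n_patients):
            out[name] = out.get(name, 0) + int(n)
        return out

    def to_dict(self) -> dict:
        return {
            "assignments": self.assignments,
            "thresholds": self.thresholds,
            "deltas": self.deltas.tolist(),
            "n_patients": self.n_patients.tolist(),
            "total_expected_delta": self.total_expected_delta,
        }


def compute_percentile_stats(
    predictions: np.ndarray,
    observed_events: np.ndarray,
    observed_event_costs: np.ndarray,
    n_bins: int = 100,
) -> PercentileStats:
    """Bin patients by predicted risk and summarize observed events.

    ``observed_event_costs`` is each patient's total cost attributable to
    undesirable events; c_e = total event cost / total events.
    """
    predictions = np.asarray(predictions, dtype=float)
    events = np.asarray(observed_events, dtype=float)
    costs = np.asarray(observed_event_costs, dtype=float)
    if not (len(predictions) == len(events) == len(costs)):
        raise ValueError("predictions, events and costs must align by patient")
    total_events = events.sum()
    if total_events <= 0:
        raise ValueError("no undesirable events observed; c_e is undefined")
    order = np.argsort(-predictions, kind="stable")
    chunks = np.array_split(order, n_bins)
    avg = np.array([events[c].mean() if len(c) else 0.0 for c in chunks])
    n = np.array([len(c) for c in chunks])
    return PercentileStats(avg, n, float(costs.sum() / total_events))


def level_delta(level: ManagementLevel, avg_n_e: float, c_e: float) -> float:
    """Expected per-patient cost change of enrollment vs no enrollment."""
    if avg_n_e < 0 or c_e < 0:
        raise ValueError("avg_n_e and c_e must be nonnegative")
    return level.c_i - avg_n_e * level.p * c_e


def _tie_key(level: ManagementLevel) -> tuple:
    # prefer the less intensive program at equal delta (conserve capacity)
    return (level.c_i, level.p, level.name)


def optimize_thresholds(
    levels: list[ManagementLevel],
    stats: PercentileStats,
    prune: bool = False,
) -> StratificationPolicy:
    """Greedy bin-by-bin assignment from the highest-risk bin down.

    Per bin, among levels whose remaining capacity fits the whole bin,
    pick the one with the smallest delta (ties toward the less intensive
    level). With ``prune=True``, once every non-null level has shown
    delta > 0 on a bin it could still accept while no capacity was used on
    that bin, remaining bins default to the null level — valid when
    avg_n_e is non-increasing, since delta is then non-decreasing.
    """
    all_levels = list(levels)
    if not any(lv.name == NULL_LEVEL_NAME for lv in all_levels):
        all_levels.append(NULL_LEVEL)
    remaining = {lv.name: (math.inf if lv.capacity is None else lv.capacity) for lv in all_levels}
    by_name = {lv.name: lv for lv in all_levels}

    assignments: list[str] = []
    deltas = np.zeros(stats.n_bins)
    stopped = False
    for b in range(stats.n_bins):
        nb = int(stats.n_patients[b])
        if stopped:
            assignments.append(NULL_LEVEL_NAME)
            deltas[b] = 0.0
            continue
        feasible = [lv for lv in all_levels if remaining[lv.name] >= nb]
        best = min(
            feasible,
            key=lambda lv: (level_delta(lv, stats.avg_n_e[b], stats.c_e), _tie_key(lv)),
        )
        d = level_delta(best, stats.avg_n_e[b], stats.c_e)
        assignments.append(best.name)
        deltas[b] = d
        remaining[best.name] -= nb
        if prune and best.name == NULL_LEVEL_NAME:
            others = [lv for lv in feasible if lv.name != NULL_LEVEL_NAME]
            if others and all(
                level_delta(lv, stats.avg_n_e[b], stats.c_e) > 0 for lv in others
            ):
                stopped = True
    return StratificationPolicy(assignments, deltas, stats.n_patients.copy(), by_name)


def exact_assignment_oracle(
    levels: list[ManagementLevel], stats: PercentileStats
) -> tuple[list[str], float]:
    """Exhaustive minimum-total-delta assignment on small instances.

    Enumerates every capacity-feasible level-per-bin assignment; intended
    as an independent check of the greedy optimizer. Refuses instances
    beyond 6 bins x 4 levels.
    """
    if stats.n_bins > 6 or len(levels) > 4:
        raise ValueError("oracle restricted to <=6 bins and <=4 levels")
    all_levels = list(levels)
    if not any(lv.name == NULL_LEVEL_NAME for lv in all_levels):
        all_levels.append(NULL_LEVEL)
    best_total = math.inf
    best_assign: list[str] | None = None
    for combo in product(all_levels, repeat=stats.n_bins):
        used: dict[str, float] = {}
        ok = True
        for lv, nb in zip(combo, stats.n_patients):
            used[lv.name] = used.get(lv.name, 0) + int(nb)
            cap = lv.capacity if lv.capacity is not None else math.inf
            if used[lv.name] > cap:
                ok = False
                break
        if not ok:
            continue
        total = sum(
            level_delta(lv, stats.avg_n_e[b], stats.c_e) * stats.n_patients[b]
            for b, lv in enumerate(combo)
        )
        if total < best_total - 1e-12:
            best_total = total
            best_assign = [lv.name for lv in combo]
    assert best_assign is not None  # null level guarantees feasibility
    return best_assign, float(best_total)


def sensitivity_thresholds(
    levels: list[ManagementLevel],
    stats: PercentileStats,
    target_level: str,
    c_i_range: tuple[float, float],
    p_range: tuple[float, float],
    n_grid: int = 5,
) -> pd.DataFrame:
    """Re-optimize over an n_grid x n_grid grid of (c_i, p) for one level.

    Each grid axis runs from the supplied minimum to maximum. Returns one
    row per cell with the implied thresholds and total expected delta.
    """
    for lo, hi in (c_i_range, p_range):
        if lo > hi:
            raise ValueError("range minimum exceeds maximum")
    base = {lv.name: lv for lv in levels}
    if target_level not in base:
        raise KeyError(f"unknown level {target_level!r}")
    rows = []
    for c_i in np.linspace(*c_i_range, n_grid):
        for p in np.linspace(*p_range, n_grid):
            varied = [
                ManagementLevel(lv.name, float(c_i), float(p), lv.capacity)
                if lv.name == target_level
                else lv
                for lv in levels
            ]
            pol = optimize_thresholds(varied, stats)
            rows.append(
                {
                    "c_i": float(c_i),
                    "p": float(p),
                    "thresholds": tuple(pol.thresholds),
                    "total_expected_delta": pol.total_expected_delta,
                    "enrolled": sum(
                        n
                        for name, n in pol.enrollment_counts().items()
                        if name != NULL_LEVEL_NAME
                    ),
                }
            )
    return pd.DataFrame(rows)
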