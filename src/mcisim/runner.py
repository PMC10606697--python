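"""Scenario sweeps and full-factorial enumeration with common random numbers.

A sweep varies one or more scenario parameters (dotted paths such as
``load.arrival_window_min`` or ``staff.radiology_assistants``) over ordered
value lists and evaluates every combination under a replication policy.
With common random numbers (CRN) enabled, replication *i* of every scenario
uses the same seed, so metric differences along an axis reflect the policy
change rather than sampling noise.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .config import STAFF_CATEGORIES, ScenarioConfig, StaffVector
from .engine import run_replication
from .outcomes import Benchmarks, replication_metrics, summarize

__all__ = [
    "FactorGrid",
    "SweepSpec",
    "factorial_grid",
    "grid_index",
    "run_scenario",
    "run_sweep",
    "fit_trend",
    "replication_seed",
]

_METRICS = ("red_critical_wait", "yellow_critical_wait", "red_total_system_time", "red_compliance", "deaths")


@dataclass(frozen=True)
class FactorGrid:
    """Ordered staffing levels per category; the cartesian product defines
    the enumeration lattice."""

    levels: dict[str, tuple[int, ...]]

    def __post_init__(self):
        unknown = set(self.levels) - set(STAFF_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown staff categories: {sorted(unknown)}")
        for cat, lv in self.levels.items():
            if len(lv) == 0:
                raise ValueError(f"{cat}: empty level list")

    @classmethod
    def staff_mix_lattice(cls) -> "FactorGrid":
        """The published three-level staff-mix lattice: minimum, baseline-ish
        midpoint and maximum headcount per category (3^7 = 2187 scenarios)."""
        return cls(
            levels={
                "medical_specialists": (8, 10, 12),
                "medical_assistants": (3, 5, 7),
                "rotation_physicians": (4, 6, 8),
                "general_nurses": (15, 20, 25),
                "surgical_assistants": (1, 2, 3),
                "surgical_nurses": (4, 6, 8),
                "radiology_assistants": (1, 2, 3),
            }
        )

    @property
    def categories(self) -> tuple[str, ...]:
        # canonical category order, first category slowest-varying
        return tuple(c for c in STAFF_CATEGORIES if c in self.levels)

    @property
    def size(self) -> int:
        n = 1
        for c in self.categories:
            n *= len(self.levels[c])
        return n

    def staff_vectors(self, base: StaffVector | None = None) -> list[StaffVector]:
        """All lattice points in enumeration order (index 1 = all levels at
        their minimum, last index = all at their maximum).  Categories absent
        from the grid keep the ``base`` headcount."""
        cats = self.categories
        base_d = base.as_dict() if base is not None else {c: 0 for c in STAFF_CATEGORIES}
        out = []
        for combo in itertools.product(*(self.levels[c] for c in cats)):
            d = dict(base_d)
            d.update(dict(zip(cats, combo)))
            out.append(StaffVector(**d))
        return out


def factorial_grid(grid: FactorGrid, base: ScenarioConfig | None = None) -> list[ScenarioConfig]:
    """Enumerate every staffing scenario of the grid, 1-based stable indexing
    (scenario #1 all-minimum, scenario #N all-maximum)."""
    if base is None:
        from .config import make_optimization_baseline

        base = make_optimization_baseline()
    vectors = grid.staff_vectors(base.staff)
    return [
        dataclasses.replace(base, label=f"grid-{i}", staff=sv)
        for i, sv in enumerate(vectors, start=1)
    ]


def grid_index(grid: FactorGrid, staff: StaffVector) -> int:
    """Inverse of the enumeration order: 1-based index of a lattice point."""
    idx = 0
    for cat in grid.categories:
        levels = grid.levels[cat]
        v = getattr(staff, cat)
        try:
            pos = levels.index(v)
        except ValueError:
            raise ValueError(f"{cat}={v} is not a grid level {levels}") from None
        idx = idx * len(levels) + pos
    return idx + 1


# ---------------------------------------------------------------------------
# dotted-path parameter access on nested frozen dataclasses


def set_by_path(cfg: ScenarioConfig, path: str, value: Any) -> ScenarioConfig:
    parts = path.split(".")

    def _set(obj, parts):
        if len(parts) == 1:
            return dataclasses.replace(obj, **{parts[0]: value})
        child = getattr(obj, parts[0])
        return dataclasses.replace(obj, **{parts[0]: _set(child, parts[1:])})

    return _set(cfg, parts)


def replication_seed(master_seed: int, rep: int, scenario_tag: int | None = None) -> np.random.SeedSequence:
    """Seed for replication ``rep``.  Under CRN ``scenario_tag`` is None and
    the seed depends only on (master_seed, rep), so the same replication of
    different scenarios shares every random substream."""
    entropy = (master_seed, rep) if scenario_tag is None else (master_seed, scenario_tag, rep)
    return np.random.SeedSequence(entropy)


def run_scenario(
    scenario: ScenarioConfig,
    reps: int | None = None,
    crn: bool = True,
    scenario_tag: int | None = None,
    benchmarks: Benchmarks = Benchmarks(),
    collect_events: bool = False,
) -> tuple[pd.DataFrame, list]:
    """Run the replication set of one scenario.

    Returns a DataFrame of per-replication metrics and the list of raw
    :class:`~mcisim.outcomes.ReplicationResult` objects.
    """
    reps = reps if reps is not None else scenario.replications
    rows = []
    results = []
    for i in range(reps):
        seed = replication_seed(scenario.seed, i, None if crn else (scenario_tag or 0))
        res = run_replication(scenario, seed, collect_events=collect_events)
        results.append(res)
        rows.append(replication_metrics(res, benchmarks))
    return pd.DataFrame(rows), results


@dataclass(frozen=True)
class SweepSpec:
    """A multi-axis sweep around a base scenario."""

    base: ScenarioConfig
    axes: tuple[tuple[str, tuple], ...]  # (dotted path, ordered values)
    reps: int = 200
    crn: bool = True
    benchmarks: Benchmarks = field(default_factory=Benchmarks)

    def scenarios(self) -> list[tuple[dict[str, Any], ScenarioConfig]]:
        paths = [a[0] for a in self.axes]
        combos = itertools.product(*(a[1] for a in self.axes))
        out = []
        for combo in combos:
            cfg = self.base
            for path, value in zip(paths, combo):
                cfg = set_by_path(cfg, path, value)
            out.append((dict(zip(paths, combo)), cfg))
        return out


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Evaluate every scenario of the sweep.

    One row per scenario: the axis values, then per metric the six summary
    statistics (mean/sd/median/min/max/range) of the per-replication means,
    plus the replication count.  Per-scenario failures are recorded in an
    ``error`` column rather than aborting the sweep.
    """
    rows = []
    for tag, (axis_values, cfg) in enumerate(spec.scenarios()):
        row: dict[str, Any] = {"scenario_index": tag + 1, **axis_values}
        try:
            df, _ = run_scenario(cfg, reps=spec.reps, crn=spec.crn, scenario_tag=tag, benchmarks=spec.benchmarks)
            for m in _METRICS:
                col = df[m].dropna()
                if col.empty:
                    continue
                for k, v in summarize(col).as_dict().items():
                    row[f"{m}_{k}"] = v
            row["n_reps"] = spec.reps
            row["error"] = ""
        except Exception as e:  # propagate per-scenario failures as data
            row["error"] = str(e)
        rows.append(row)
    return pd.DataFrame(rows)


def fit_trend(xs, ys) -> tuple[float, float, float]:
    """Ordinary least-squares line through scenario results.

    Returns (slope, intercept, R^2); used e.g. for the marginal waiting-time
    increase per additional severely injured patient.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 2 or np.all(xs == xs[0]):
        raise ValueError("need at least two distinct x values")
    res = _sstats.linregress(xs, ys)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
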