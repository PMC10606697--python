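"""Constrained staff-mix simulation-optimization on an integer lattice.

The decision problem: choose the staffing vector with the smallest total
headcount whose mean total system time for severely injured patients stays
below a limit (default 200 minutes), ties broken by the smaller metric.  The
search emulates metaheuristic simulation-optimization: scatter-search-style
recombination over the lattice with a tabu memory of visited points,
systematic diversification (so a budget covering the whole space degenerates
to exact enumeration), and noise-aware acceptance in which a candidate
displaces the incumbent only when its confidence interval lies below the
incumbent's.  An enumeration oracle over the full lattice is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import ScenarioConfig, StaffVector
from .engine import run_replication
from .outcomes import replication_metrics
from .runner import FactorGrid, replication_seed

__all__ = [
    "SearchSpace",
    "ObjectiveSpec",
    "ReplicationPolicy",
    "PointEstimate",
    "OptResult",
    "evaluate_point",
    "enumerate_rank",
    "optimize",
]


@dataclass(frozen=True)
class SearchSpace:
    """Finite integer staff lattice (ordered levels per category)."""

    grid: FactorGrid
    base: StaffVector  # headcounts for categories not in the grid

    @property
    def size(self) -> int:
        return self.grid.size

    def points(self) -> list[StaffVector]:
        return self.grid.staff_vectors(self.base)

    def contains(self, staff: StaffVector) -> bool:
        for cat in self.grid.categories:
            if getattr(staff, cat) not in self.grid.levels[cat]:
                return False
        return True


@dataclass(frozen=True)
class ObjectiveSpec:
    """Minimize total headcount subject to the mean red total-system-time
    constraint; at equal headcount the smaller metric wins."""

    limit: float = 200.0
    confidence: float = 0.95

    def __post_init__(self):
        if self.limit <= 0:
            raise ValueError("constraint limit must be positive")


@dataclass(frozen=True)
class ReplicationPolicy:
    """Fixed or sequential replication allocation per evaluated point."""

    mode: str = "fixed"  # fixed | sequential
    reps: int = 50
    confidence: float = 0.95
    rel_halfwidth: float = 0.05
    pilot: int = 10
    max_reps: int = 5000
    confirmation_factor: int = 2  # extra screening multiple for incumbents


@dataclass
class PointEstimate:
    staff: StaffVector
    mean: float
    halfwidth: float
    n_reps: int


@dataclass
class OptResult:
    best_staff: StaffVector
    estimate: float
    halfwidth: float
    feasible: bool
    space_infeasible: bool
    n_evaluations: int
    trace: list[dict] = field(default_factory=list)


def _metric_stream(staff: StaffVector, scenario: ScenarioConfig, max_reps: int):
    cfg = scenario.replace(staff=staff)
    for i in range(max_reps):
        res = run_replication(cfg, replication_seed(scenario.seed, i), collect_events=False)
        yield replication_metrics(res)["red_total_system_time"]


def evaluate_point(
    staff: StaffVector,
    scenario: ScenarioConfig,
    policy: ReplicationPolicy = ReplicationPolicy(),
    n_reps: int | None = None,
) -> PointEstimate:
    """Estimate the mean red total system time of a staffing vector.

    Replications use common random numbers (seeds depend only on the
    scenario's master seed and the replication index), so evaluations of
    different staffing vectors are paired.  Replications with no surviving
    severely injured patient contribute no metric value.
    """
    if policy.mode == "sequential" and n_reps is None:
        from .outcomes import required_replications

        values: list[float] = []

        def _capture():
            for v in _metric_stream(staff, scenario, policy.max_reps):
                if not math.isnan(v):
                    values.append(v)
                    yield v

        required_replications(
            _capture(),
            confidence=policy.confidence,
            rel_halfwidth=policy.rel_halfwidth,
            pilot=policy.pilot,
            max_n=policy.max_reps,
        )
    else:
        r = n_reps if n_reps is not None else policy.reps
        values = [v for v in _metric_stream(staff, scenario, r) if not math.isnan(v)]
    if not values:
        raise ValueError(f"staffing {staff.as_tuple()}: no replication produced a metric value")
    n = len(values)
    mean = float(np.mean(values))
    if n > 1:
        hw = float(stats.t.ppf(0.5 + policy.confidence / 2, n - 1) * np.std(values, ddof=1) / math.sqrt(n))
    else:
        hw = 0.0
    return PointEstimate(staff=staff, mean=mean, halfwidth=hw, n_reps=n)


def _rank_key(est: PointEstimate, objective: ObjectiveSpec):
    feasible = est.mean < objective.limit
    if feasible:
        return (0, est.staff.total, est.mean)
    return (1, est.mean, est.staff.total)  # least-violating first among infeasible


def enumerate_rank(
    space: SearchSpace,
    scenario: ScenarioConfig,
    objective: ObjectiveSpec = ObjectiveSpec(),
    policy: ReplicationPolicy = ReplicationPolicy(),
    evaluator=None,
) -> list[PointEstimate]:
    """Evaluate every lattice point and rank feasible points by
    (headcount, metric); infeasible points follow, least-violating first."""
    points = space.points()
    if not points:
        raise ValueError("empty search space")
    ev = evaluator or (lambda s, n=None: evaluate_point(s, scenario, policy, n_reps=n))
    estimates = [_coerce(ev(p), p) for p in points]
    estimates.sort(key=lambda e: _rank_key(e, objective))
    return estimates


def _coerce(result, staff: StaffVector) -> PointEstimate:
    """Accept surrogate evaluators returning a bare number."""
    if isinstance(result, PointEstimate):
        return result
    return PointEstimate(staff=staff, mean=float(result), halfwidth=0.0, n_reps=1)


def optimize(
    space: SearchSpace,
    scenario: ScenarioConfig,
    objective: ObjectiveSpec = ObjectiveSpec(),
    budget: int = 100,
    seed: int = 0,
    policy: ReplicationPolicy = ReplicationPolicy(),
    evaluator=None,
) -> OptResult:
    """Population search over the staff lattice, deterministic given ``seed``.

    Mechanics: an initial population of the lattice corners plus random
    points; candidates are generated by rounding midpoints of elite pairs to
    the nearest lattice level and by single-coordinate level steps of the
    incumbent; a tabu set bars re-evaluation, with diversification drawing
    unvisited points in a seed-determined order whenever proposals are
    exhausted.  A candidate displaces the incumbent only when its confidence
    interval lies below the incumbent's (screening replications first,
    confirmation replications before acceptance).  The returned point is the
    best evaluated point under the objective's ranking.
    """
    points = space.points()
    if not points:
        raise ValueError("empty search space")
    if budget < 1:
        raise ValueError("budget must allow at least one evaluation")
    ev = evaluator or (lambda s, n=None: evaluate_point(s, scenario, policy, n_reps=n))
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, 0x5EED))))

    index = {p.as_tuple(): i for i, p in enumerate(points)}
    unvisited = list(rng.permutation(len(points)))
    visited: dict[tuple, PointEstimate] = {}
    trace: list[dict] = []

    def _evaluate(staff: StaffVector, n=None) -> PointEstimate:
        est = _coerce(ev(staff, n) if n is not None else ev(staff), staff)
        visited[staff.as_tuple()] = est
        unvisited_discard(staff)
        trace.append(
            {
                "staff": staff.as_tuple(),
                "headcount": staff.total,
                "mean": est.mean,
                "halfwidth": est.halfwidth,
                "n_reps": est.n_reps,
            }
        )
        return est

    def unvisited_discard(staff: StaffVector):
        i = index[staff.as_tuple()]
        try:
            unvisited.remove(i)
        except ValueError:
            pass

    def _next_unvisited() -> StaffVector | None:
        while unvisited:
            return points[unvisited[0]]
        return None

    def _midpoint(a: StaffVector, b: StaffVector) -> StaffVector:
        d = {}
        for cat in a.as_dict():
            if cat in space.grid.levels:
                mid = (getattr(a, cat) + getattr(b, cat)) / 2
                levels = space.grid.levels[cat]
                d[cat] = min(levels, key=lambda lv: (abs(lv - mid), lv))
            else:
                d[cat] = getattr(a, cat)
        return StaffVector(**d)

    def _step(a: StaffVector) -> StaffVector:
        cats = space.grid.categories
        cat = cats[int(rng.integers(len(cats)))]
        levels = space.grid.levels[cat]
        pos = levels.index(getattr(a, cat))
        new_pos = max(0, min(len(levels) - 1, pos + (1 if rng.uniform() < 0.5 else -1)))
        return StaffVector(**{**a.as_dict(), cat: levels[new_pos]})

    # initial population: corners plus seed-determined random points
    corners = [points[0], points[-1]]
    pop_target = min(max(4, min(10, len(points))), budget)
    initial = []
    for p in corners:
        if p.as_tuple() not in {q.as_tuple() for q in initial}:
            initial.append(p)
    while len(initial) < pop_target and len(initial) < len(points):
        cand = points[int(rng.integers(len(points)))]
        if cand.as_tuple() not in {q.as_tuple() for q in initial}:
            initial.append(cand)

    incumbent: PointEstimate | None = None
    for p in initial:
        if len(trace) >= budget:
            break
        est = _evaluate(p)
        if incumbent is None or _accepts(est, incumbent, objective):
            incumbent = est

    while len(trace) < budget and len(visited) < len(points):
        elites = sorted(visited.values(), key=lambda e: _rank_key(e, objective))[:4]
        proposals: list[StaffVector] = []
        if len(elites) >= 2:
            proposals.append(_midpoint(elites[0].staff, elites[1].staff))
        if elites:
            proposals.append(_step(elites[0].staff))
        chosen = None
        for cand in proposals:
            if space.contains(cand) and cand.as_tuple() not in visited:
                chosen = cand
                break
        if chosen is None:
            chosen = _next_unvisited()  # tabu-driven diversification
        if chosen is None:
            break
        est = _evaluate(chosen)
        if incumbent is not None and _beats_with_confidence(est, incumbent, objective):
            # confirmation stage: re-estimate the challenger at higher effort
            if est.halfwidth > 0 and policy.confirmation_factor > 1 and len(trace) < budget:
                est = _evaluate(chosen, n=est.n_reps * policy.confirmation_factor)
        if incumbent is None or _accepts(est, incumbent, objective):
            incumbent = est

    best = min(visited.values(), key=lambda e: _rank_key(e, objective))
    feasible = best.mean < objective.limit
    return OptResult(
        best_staff=best.staff,
        estimate=best.mean,
        halfwidth=best.halfwidth,
        feasible=feasible,
        space_infeasible=not feasible,
        n_evaluations=len(trace),
        trace=trace,
    )


def _accepts(cand: PointEstimate, inc: PointEstimate, objective: ObjectiveSpec) -> bool:
    """Noise-aware acceptance: on feasibility/headcount the comparison is
    exact; on the metric the candidate's confidence interval must lie
    entirely below the incumbent's."""
    kc, ki = _rank_key(cand, objective), _rank_key(inc, objective)
    if kc[:2] != ki[:2]:
        return kc[:2] < ki[:2]
    return cand.mean + cand.halfwidth < inc.mean - inc.halfwidth


_beats_with_confidence = _accepts
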