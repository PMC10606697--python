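"""Outcome measures, benchmark compliance and replication statistics.

The key clinical outcome is the *waiting time for critical treatment*: for
surgical patients the time from hospital arrival to the start of surgery,
for non-surgical patients the time to the start of their first clinical
treatment.  Benchmarks: surgery should start within 120 minutes for severely
injured (red) and within 720 minutes for moderately injured (yellow)
patients; the staff-mix optimization constrains the mean *total system time*
(arrival to exit from the trauma pathway) of red patients to 200 minutes.

Patients who die before their defining event are excluded from waiting-time
means and reported as a separate death count.  A re-triaged patient counts
under the category they held at the defining event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Benchmarks",
    "PatientRecord",
    "ReplicationResult",
    "SummaryRow",
    "critical_wait",
    "total_system_time",
    "compliance_fraction",
    "summarize",
    "required_replications",
    "replication_metrics",
    "pooled_critical_waits",
    "IncompleteRecordError",
]


class IncompleteRecordError(ValueError):
    """A record is missing the event that defines the requested metric."""


@dataclass(frozen=True)
class Benchmarks:
    """Medically motivated waiting-time limits (minutes)."""

    red_surgery_limit: float = 120.0
    yellow_surgery_limit: float = 720.0
    red_total_system_limit: float = 200.0

    def __post_init__(self):
        if min(self.red_surgery_limit, self.yellow_surgery_limit, self.red_total_system_limit) <= 0:
            raise ValueError("benchmarks must be positive")
        if self.red_surgery_limit >= self.yellow_surgery_limit:
            raise ValueError("red limit must be below the yellow limit")

    def limit_for(self, category: str) -> float:
        return {"red": self.red_surgery_limit, "yellow": self.yellow_surgery_limit}[category]


@dataclass(frozen=True)
class PatientRecord:
    """One casualty's category history and timestamp trail."""

    patient_id: int
    initial_category: str
    final_category: str
    arrival: float
    first_treatment_start: float | None
    category_at_first_treatment: str | None
    surgery_start: float | None
    category_at_surgery: str | None
    needs_surgery: bool
    exit_time: float | None
    death_time: float | None
    terminal: str  # EXITED | DECEASED
    h_final: float
    n_retriage: int = 0

    @property
    def defining_category(self) -> str | None:
        """Category held at the event that defines the critical wait."""
        if self.surgery_start is not None:
            return self.category_at_surgery
        return self.category_at_first_treatment


@dataclass
class ReplicationResult:
    """Per-replication output: patient records, resource occupancy fractions,
    staff workload fractions, and the death count."""

    records: list[PatientRecord]
    utilization: dict[str, float]
    staff_workload: dict[str, float]
    deaths: int
    end_time: float
    start_time: float
    events: list[dict] | None = None


def critical_wait(record: PatientRecord) -> float | None:
    """Waiting time for critical treatment, or None for a patient who died
    before the defining event (tallied separately, never averaged)."""
    if record.surgery_start is not None:
        return record.surgery_start - record.arrival
    if record.needs_surgery and record.death_time is not None:
        return None
    if record.first_treatment_start is not None:
        return record.first_treatment_start - record.arrival
    if record.death_time is not None:
        return None
    raise IncompleteRecordError(
        f"patient {record.patient_id}: no defining event recorded and patient not deceased"
    )


def total_system_time(record: PatientRecord) -> float:
    """Arrival to exit from the trauma pathway."""
    if record.exit_time is None:
        raise IncompleteRecordError(f"patient {record.patient_id} still in the system")
    return record.exit_time - record.arrival


def _eligible_waits(records, category: str) -> list[float]:
    waits = []
    for r in records:
        if r.initial_category == "green":
            continue
        w = critical_wait(r)
        if w is None:
            continue
        if r.defining_category == category:
            waits.append(w)
    return waits


def compliance_fraction(records, category: str, benchmarks: Benchmarks = Benchmarks()) -> float:
    """Share of eligible patients of a category whose critical wait meets the
    category's benchmark."""
    waits = _eligible_waits(records, category)
    if not waits:
        raise ValueError(f"no eligible {category} patients")
    limit = benchmarks.limit_for(category)
    return sum(w <= limit for w in waits) / len(waits)


@dataclass(frozen=True)
class SummaryRow:
    """Mean / sd / median / min / max / range of one metric."""

    mean: float
    sd: float
    median: float
    min: float
    max: float
    range: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "min": self.min,
            "max": self.max,
            "range": self.range,
            "n": self.n,
        }


def summarize(samples) -> SummaryRow:
    """Location and spread statistics; sample sd uses the n-1 denominator."""
    x = np.asarray(list(samples), dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    return SummaryRow(
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        median=float(np.median(x)),
        min=float(np.min(x)),
        max=float(np.max(x)),
        range=float(np.max(x) - np.min(x)),
        n=int(x.size),
    )


def required_replications(
    stream,
    confidence: float = 0.95,
    rel_halfwidth: float = 0.05,
    pilot: int = 10,
    max_n: int = 1_000_000,
) -> int:
    """Sequential stopping rule for replication control.

    Consumes per-replication means from ``stream`` (any iterable) and returns
    the smallest n >= ``pilot`` at which the t-based confidence interval
    half-width of the running mean is within ``rel_halfwidth`` of its
    absolute value.  Deterministic given the stream.
    """
    if not (0 < confidence < 1):
        raise ValueError("confidence must be in (0, 1)")
    if rel_halfwidth <= 0:
        raise ValueError("rel_halfwidth must be positive")
    if pilot < 2:
        raise ValueError("pilot size must be at least 2")
    n = 0
    s = 0.0
    ss = 0.0
    for x in stream:
        n += 1
        s += x
        ss += x * x
        if n < pilot:
            continue
        mean = s / n
        var = max(0.0, (ss - n * mean * mean) / (n - 1))
        if var == 0.0:
            return n
        if mean == 0.0:
            raise ValueError(
                "running mean is zero with nonzero variance: relative precision undefined; use an absolute-precision rule"
            )
        hw = stats.t.ppf(0.5 + confidence / 2.0, n - 1) * math.sqrt(var / n)
        if hw <= rel_halfwidth * abs(mean):
            return n
        if n >= max_n:
            break
    raise ValueError(f"stream exhausted after {n} replications without reaching the target precision")


# ---------------------------------------------------------------------------
# per-replication metric extraction used by sweeps and the optimizer


def replication_metrics(result: ReplicationResult, benchmarks: Benchmarks = Benchmarks()) -> dict[str, float]:
    """Scalar metrics of one replication.

    Waiting-time means are over patients classified by their category at the
    defining event; total system time is over patients who arrived severely
    injured and exited alive.  NaN marks a metric with no eligible patient in
    this replication.
    """
    red_waits = _eligible_waits(result.records, "red")
    yellow_waits = _eligible_waits(result.records, "yellow")
    red_system = [
        total_system_time(r)
        for r in result.records
        if r.initial_category == "red" and r.exit_time is not None
    ]
    limit = benchmarks.red_surgery_limit
    return {
        "red_critical_wait": float(np.mean(red_waits)) if red_waits else float("nan"),
        "yellow_critical_wait": float(np.mean(yellow_waits)) if yellow_waits else float("nan"),
        "red_total_system_time": float(np.mean(red_system)) if red_system else float("nan"),
        "red_compliance": (sum(w <= limit for w in red_waits) / len(red_waits)) if red_waits else float("nan"),
        "deaths": float(result.deaths),
    }


def pooled_critical_waits(results, category: str) -> list[float]:
    """Patient-level critical waits pooled across replications (the shape of
    the published per-scenario summary tables)."""
    waits: list[float] = []
    for res in results:
        waits.extend(_eligible_waits(res.records, category))
    return waits
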