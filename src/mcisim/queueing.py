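"""Closed-form multi-server queueing results used as simulation oracles."""

from __future__ import annotations

import math

__all__ = ["erlang_c", "mmc_mean_wait", "mmc_scenario"]


def erlang_c(c: int, offered_load: float) -> float:
    """Erlang-C probability that an arriving customer must wait in an
    M/M/c queue with offered load a = lambda/mu (requires a < c)."""
    if c < 1:
        raise ValueError("need at least one server")
    a = offered_load
    if not (0 <= a < c):
        raise ValueError("offered load must satisfy 0 <= a < c for stability")
    # sum_{k<c} a^k/k! computed iteratively
    term = 1.0
    s = 1.0
    for k in range(1, c):
        term *= a / k
        s += term
    top = term * a / c / (1.0 - a / c)
    return top / (s + top)


def mmc_mean_wait(lam: float, mu: float, c: int) -> float:
    """Mean time in queue W_q of an M/M/c queue (minutes if rates are
    per-minute)."""
    if lam <= 0 or mu <= 0:
        raise ValueError("rates must be positive")
    a = lam / mu
    if a >= c:
        raise ValueError("unstable queue: lambda/mu >= c")
    return erlang_c(c, a) / (c * mu - lam)


def mmc_scenario(lam: float, mu: float, c: int, n_arrivals: int, seed: int = 0):
    """Degenerate scenario reducing the hospital engine to a single-station
    M/M/c queue: moderately injured patients only, exponential examination
    service, no triage, no imaging, no surgery, no health dynamics, ``c``
    treatment slots and no staff requirement.

    The engine's mean critical wait on this scenario is comparable with
    :func:`mmc_mean_wait` — the standard analytic validation of the
    event-driven core.
    """
    import dataclasses

    from .config import (
        Calibration,
        HealthDynamics,
        PatientLoad,
        ResourceSet,
        ScenarioConfig,
        ServiceTime,
        StaffVector,
    )

    cal = Calibration(
        service={
            **Calibration().service,
            "yellow_exam": ServiceTime("exponential", 1.0 / mu),
            "transfer": ServiceTime("fixed", 0.0),
        },
        health=HealthDynamics(d_red=0.0, d_yellow=0.0, d_green=0.0),
        staffing={**{k: [list(s) for s in v] for k, v in Calibration().staffing.items()}, "yellow_exam": []},
        p_yellow_surgery=0.0,
        p_imaging_yellow=0.0,
        routine_day_rate_per_h=0.0,
        routine_night_rate_per_h=0.0,
        triage_enabled=False,
    )
    window = n_arrivals / lam  # expected makespan at arrival rate lambda
    return ScenarioConfig(
        label=f"mmc-c{c}",
        staff=StaffVector(0, 0, 0, 0, 0, 0, 0),
        load=PatientLoad(0, n_arrivals, 0, arrival_window_min=window, incident_time_of_day=0.0),
        resources=dataclasses.replace(ResourceSet(), n_yellow_treatment_slots=c),
        calibration=cal,
        seed=seed,
    )
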