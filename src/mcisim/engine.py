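"""Event-driven core of the mass-casualty-incident hospital model.

The engine simulates triaged trauma-patient flow at the individual-patient
level.  Patients arrive per triage category with exponential inter-arrival
times, are triaged at the emergency-department entrance, and follow
category-specific pathways through resuscitation bays, imaging machines,
operating rooms and outpatient treatment slots.  Each task seizes a staff
multiset, a room and (for imaging) a machine simultaneously and releases all
of them at completion; queues are non-preemptive priority queues, red before
yellow before green and first-come-first-served within a category.

Health is a score in [0, 99] (99 = perfect health, 0 = death).  While a
patient awaits their first clinical treatment the score falls at the
category's deterioration rate; deterioration is piecewise linear, so
threshold crossings (progressive re-triage and death) are scheduled at their
exact times rather than sampled on a fixed tick.  During treatment the score
rises; a patient whose score reaches 0 turns black (deceased), an absorbing
state that releases nothing and is removed from every queue.

Randomness is organized as one independent substream per stochastic purpose
(arrivals per category, each service-time family, each Bernoulli decision),
all derived from a single replication seed.  Service times and pathway coin
flips are pre-drawn per patient in a scenario-independent order, so two
scenarios simulated with the same replication seed share common random
numbers and their metric differences reflect policy, not noise.
"""

from __future__ import annotations

import heapq
import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .config import Calibration, PatientLoad, ScenarioConfig, STAFF_CATEGORIES, validate_config
from .outcomes import PatientRecord, ReplicationResult

__all__ = [
    "RED",
    "YELLOW",
    "GREEN",
    "BLACK",
    "Patient",
    "TaskRequirement",
    "generate_arrivals",
    "retriage",
    "update_health",
    "required_green_supervision",
    "routine_or_load",
    "run_replication",
    "Simulation",
]

RED = "red"
YELLOW = "yellow"
GREEN = "green"
BLACK = "black"

_PRIORITY = {RED: 0, YELLOW: 1, GREEN: 2}

# Stations in grant order; red-critical stations are attempted first when
# several queues compete for freed resources.
STATION_ORDER = ("resus", "surgery", "ct", "xray", "yellow_exam", "triage")
# health improves during treatment; diagnostic imaging holds it constant
_TREATMENT_STATIONS = frozenset({"resus", "yellow_exam", "surgery"})

# Registry of named random substreams, in fixed spawn order.  The layout is
# part of the reproducibility contract: common-random-number comparisons
# across scenarios rely on it.
_STREAMS = (
    "arr_red",
    "arr_yellow",
    "arr_green",
    "h0_red",
    "h0_yellow",
    "h0_green",
    "svc_triage",
    "svc_red_stabilization",
    "svc_yellow_exam",
    "svc_ct",
    "svc_xray",
    "svc_red_surgery",
    "svc_yellow_surgery",
    "svc_transfer",
    "bern_surgery",
    "bern_imaging",
    "bern_ct",
    "bern_downgrade",
    "routine",
)


def _spawn_streams(seed) -> dict[str, np.random.Generator]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(_STREAMS))
    return {name: np.random.Generator(np.random.PCG64(c)) for name, c in zip(_STREAMS, children)}


@dataclass(frozen=True)
class TaskRequirement:
    """Everything a task seizes: staff slots (each slot lists acceptable
    categories in preference order), one room out of the given options, and
    the service-time family that determines its duration."""

    station: str
    staff_slots: tuple[tuple[str, ...], ...]
    room_options: tuple[str, ...]
    service_key: str


class Patient:
    """One casualty: triage state, health score, pathway flags, timestamps."""

    __slots__ = (
        "id",
        "initial_category",
        "category",
        "h",
        "arrival",
        "needs_surgery",
        "needs_imaging",
        "ct_indicated",
        "downgrade_eligible",
        "durations",
        "state",
        "triage_done",
        "first_treatment_start",
        "category_at_first_treatment",
        "surgery_start",
        "category_at_surgery",
        "imaged",
        "imaging_station",
        "transfer_done",
        "exit_time",
        "death_time",
        "h_anchor",
        "health_version",
        "queue_token",
        "n_retriage",
    )

    def __init__(self, pid, category, h0, arrival, needs_surgery, needs_imaging, ct_indicated, downgrade_eligible, durations):
        self.id = pid
        self.initial_category = category
        self.category = category
        self.h = float(h0)
        self.arrival = float(arrival)
        self.needs_surgery = bool(needs_surgery)
        self.needs_imaging = bool(needs_imaging)
        self.ct_indicated = bool(ct_indicated)
        self.downgrade_eligible = bool(downgrade_eligible)
        self.durations = durations  # service_key -> pre-drawn minutes
        self.state = "pre_arrival"
        self.triage_done = False
        self.first_treatment_start = None
        self.category_at_first_treatment = None
        self.surgery_start = None
        self.category_at_surgery = None
        self.imaged = False
        self.imaging_station = None
        self.transfer_done = False
        self.exit_time = None
        self.death_time = None
        self.h_anchor = float(arrival)
        self.health_version = 0
        self.queue_token = None
        self.n_retriage = 0


def retriage(h: float, dynamics) -> str:
    """Map a health score to its triage category.

    0 is death (black); below ``theta_red`` the patient is severely injured
    (red); below ``theta_yellow`` moderately injured (yellow); otherwise
    slightly injured (green).
    """
    if not (0.0 <= h <= 99.0):
        raise ValueError(f"health score {h} outside [0, 99]")
    if h == 0.0:
        return BLACK
    if h < dynamics.theta_red:
        return RED
    if h < dynamics.theta_yellow:
        return YELLOW
    return GREEN


def update_health(patient: Patient, dt: float, waiting: bool, dynamics) -> float:
    """Advance a patient's health score over ``dt`` minutes.

    Waiting patients deteriorate at their current category's rate; treated
    patients improve at ``r_improve``.  The score is clamped to [0, 99]; a
    waiting patient reaching 0 becomes black (absorbing).
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if patient.category == BLACK:
        raise ValueError("black is absorbing; no further health updates")
    if waiting:
        rate = dynamics.rate_for(patient.category)
        patient.h = max(0.0, patient.h - rate * dt)
        if patient.h == 0.0:
            patient.category = BLACK
    else:
        patient.h = min(99.0, patient.h + dynamics.r_improve * dt)
    return patient.h


def required_green_supervision(n_green_present: int, greens_per_nurse: int = 10, greens_per_rotation_physician: int = 25) -> tuple[int, int]:
    """Staff locked in the dining hall while slightly injured patients wait
    there: one nurse per 10 and one rotation physician per 25 patients."""
    if n_green_present < 0:
        raise ValueError("negative patient count")
    if n_green_present == 0:
        return (0, 0)
    return (
        math.ceil(n_green_present / greens_per_nurse),
        math.ceil(n_green_present / greens_per_rotation_physician),
    )


def generate_arrivals(load: PatientLoad, streams) -> list[tuple[float, str]]:
    """Time-ordered arrival events ``(time, category)``.

    Within each category with ``n > 0`` patients, inter-arrival times are
    i.i.d. exponential with mean ``arrival_window_min / n`` starting at the
    incident time, so the arrival window is the *expected* makespan of each
    category's arrival process, not a hard cutoff.

    ``streams`` maps category name to a numpy Generator (a single Generator
    is also accepted and then shared by all categories).
    """
    if not isinstance(streams, dict):
        streams = {RED: streams, YELLOW: streams, GREEN: streams}
    t0 = load.incident_time_of_day
    events: list[tuple[float, str]] = []
    for cat, n in zip((RED, YELLOW, GREEN), load.counts()):
        if n <= 0:
            continue
        gaps = streams[cat].exponential(load.arrival_window_min / n, size=n)
        for t in t0 + np.cumsum(gaps):
            events.append((float(t), cat))
    events.sort(key=lambda e: (e[0], _PRIORITY[e[1]]))
    return events


def _routine_rate(calibration: Calibration, t: float) -> float:
    """Background operating-room case intensity (per minute) at clock ``t``."""
    tod = t % 1440.0
    per_h = (
        calibration.routine_day_rate_per_h
        if calibration.routine_day_start <= tod < calibration.routine_day_end
        else calibration.routine_night_rate_per_h
    )
    return per_h / 60.0


def routine_or_load(calibration: Calibration, t_start: float, t_end: float, stream) -> list[tuple[float, float]]:
    """Background (routine) operating-room cases over a time window.

    Draws case start times from a time-of-day-modulated Poisson process (day
    versus night intensity, by thinning) with lognormal case durations;
    returns ``(start, duration)`` pairs.  These cases occupy central
    operating rooms only — the trauma theatres are reserved for incident
    surgery.  Zero intensity yields no events.
    """
    cal = calibration
    max_rate = max(cal.routine_day_rate_per_h, cal.routine_night_rate_per_h) / 60.0
    if max_rate <= 0:
        return []
    out = []
    t = t_start
    while True:
        t += stream.exponential(1.0 / max_rate)
        if t >= t_end:
            return out
        if stream.uniform() <= _routine_rate(cal, t) / max_rate:
            out.append((t, float(cal.service["routine_or_case"].sample(stream))))


class _Pool:
    """A capacity-constrained resource with busy-time accounting and an
    optional reservation (staff held back for dining-hall supervision)."""

    __slots__ = ("name", "capacity", "busy", "reserved", "busy_time", "reserved_time", "_last")

    def __init__(self, name, capacity, t0):
        self.name = name
        self.capacity = int(capacity)
        self.busy = 0
        self.reserved = 0
        self.busy_time = 0.0
        self.reserved_time = 0.0
        self._last = t0

    def _advance(self, t):
        dt = t - self._last
        if dt > 0:
            self.busy_time += self.busy * dt
            self.reserved_time += min(self.reserved, self.capacity - self.busy) * dt
            self._last = t

    def change_busy(self, t, delta):
        self._advance(t)
        self.busy += delta
        if self.busy < 0 or self.busy > self.capacity:
            raise RuntimeError(f"pool {self.name}: occupancy {self.busy} outside [0, {self.capacity}]")

    def set_reserved(self, t, value):
        self._advance(t)
        self.reserved = value

    def available(self) -> int:
        return max(0, self.capacity - self.busy - self.reserved)

    def free(self) -> int:
        return self.capacity - self.busy


class Simulation:
    """One replication of a scenario.  Deterministic given (scenario, seed)."""

    def __init__(self, scenario: ScenarioConfig, seed, collect_events: bool = True, max_events: int | None = None):
        violations = validate_config(scenario)
        if violations:
            raise ValueError("invalid scenario: " + "; ".join(violations))
        self.scenario = scenario
        self.cal: Calibration = scenario.calibration
        self.collect_events = collect_events
        self.seed = seed
        self.t0 = scenario.load.incident_time_of_day
        self.clock = self.t0
        n_total = sum(scenario.load.counts())
        self.max_events = max_events if max_events is not None else 500_000 + 60 * n_total
        self._events_processed = 0
        self._seq = 0
        self.heap: list = []
        self.queues: dict[str, list] = {s: [] for s in STATION_ORDER}
        self.log: list[dict] = []
        self.n_hall = 0
        self._hall: list[Patient] = []
        self.deaths = 0
        self._routine_active = 0
        self._init_pools()
        self._init_patients()
        self._init_routine()

    # -- setup ------------------------------------------------------------

    def _init_pools(self):
        r = self.scenario.resources
        t0 = self.t0
        self.pools: dict[str, _Pool] = {}
        for cat in STAFF_CATEGORIES:
            self.pools[cat] = _Pool(cat, getattr(self.scenario.staff, cat), t0)
        self.pools["resus_bay"] = _Pool("resus_bay", r.n_resus_bays, t0)
        self.pools["yellow_slot"] = _Pool("yellow_slot", r.n_yellow_treatment_slots, t0)
        self.pools["trauma_or"] = _Pool("trauma_or", r.n_trauma_or, t0)
        self.pools["central_or"] = _Pool("central_or", r.n_central_or_usable, t0)
        self.pools["ct_machine"] = _Pool("ct_machine", r.n_ct, t0)
        self.pools["xray_machine"] = _Pool("xray_machine", r.n_xray, t0)

    def _init_patients(self):
        cal = self.cal
        load = self.scenario.load
        streams = _spawn_streams(self.seed)
        self.streams = streams
        arrival_times: dict[str, np.ndarray] = {}
        for cat, n, skey in ((RED, load.n_red, "arr_red"), (YELLOW, load.n_yellow, "arr_yellow"), (GREEN, load.n_green, "arr_green")):
            if n > 0:
                gaps = streams[skey].exponential(load.arrival_window_min / n, size=n)
                arrival_times[cat] = self.t0 + np.cumsum(gaps)
            else:
                arrival_times[cat] = np.empty(0)

        n_total = sum(load.counts())
        self.patients: list[Patient] = []
        self.n_unsettled = n_total
        # pre-draw per patient, category-major order (red, yellow, green),
        # each family from its own substream: the CRN layout
        durs = {}
        for key in ("triage", "red_stabilization", "yellow_exam", "ct", "xray", "red_surgery", "yellow_surgery", "transfer"):
            durs[key] = cal.service[key].sample(streams[f"svc_{key}"], size=n_total) if n_total else np.empty(0)
        u_surgery = streams["bern_surgery"].uniform(size=n_total)
        u_imaging = streams["bern_imaging"].uniform(size=n_total)
        u_ct = streams["bern_ct"].uniform(size=n_total)
        u_down = streams["bern_downgrade"].uniform(size=n_total)

        pid = 0
        for cat in (RED, YELLOW, GREEN):
            lo, hi = cal.init_health[cat]
            n = {RED: load.n_red, YELLOW: load.n_yellow, GREEN: load.n_green}[cat]
            h0s = streams[f"h0_{cat}"].uniform(lo, hi, size=n) if n else np.empty(0)
            p_surg = {RED: cal.p_red_surgery, YELLOW: cal.p_yellow_surgery, GREEN: 0.0}[cat]
            p_img = {RED: cal.p_imaging_red, YELLOW: cal.p_imaging_yellow, GREEN: 0.0}[cat]
            p_ct = {RED: cal.p_ct_red, YELLOW: cal.p_ct_yellow, GREEN: 0.0}[cat]
            for i in range(n):
                p = Patient(
                    pid,
                    cat,
                    h0s[i],
                    arrival_times[cat][i],
                    needs_surgery=u_surgery[pid] < p_surg,
                    needs_imaging=u_imaging[pid] < p_img,
                    ct_indicated=u_ct[pid] < p_ct,
                    downgrade_eligible=u_down[pid] < cal.p_ct_downgrade_eligible,
                    durations={k: float(v[pid]) for k, v in durs.items()},
                )
                self.patients.append(p)
                self._push(p.arrival, "arrival", p.id)
                pid += 1

    def _init_routine(self):
        cal = self.cal
        if cal.routine_day_rate_per_h <= 0 and cal.routine_night_rate_per_h <= 0:
            return
        rng = self.streams["routine"]
        # cases from the pre-incident window still running at the incident
        # time occupy central operating rooms from the start
        for t, dur in routine_or_load(cal, self.t0 - 480.0, self.t0, rng):
            if t + dur > self.t0 and self.pools["central_or"].free() > 0:
                self.pools["central_or"].change_busy(self.t0, +1)
                self._routine_active += 1
                self._push(t + dur, "routine_end", None)
                self._log(self.t0, None, "seize", "routine_or", {"central_or": 1})
        self._schedule_next_routine(self.t0)

    def _routine_rate(self, t: float) -> float:
        return _routine_rate(self.cal, t)

    def _schedule_next_routine(self, t: float):
        cal = self.cal
        rng = self.streams["routine"]
        max_rate = max(cal.routine_day_rate_per_h, cal.routine_night_rate_per_h) / 60.0
        if max_rate <= 0:
            return
        while True:
            t += rng.exponential(1.0 / max_rate)
            if rng.uniform() <= self._routine_rate(t) / max_rate:
                break
        self._push(t, "routine_arrival", None)

    # -- event plumbing ---------------------------------------------------

    def _push(self, t, kind, payload):
        self._seq += 1
        heapq.heappush(self.heap, (t, self._seq, kind, payload))

    def _log(self, t, patient, event, station=None, resources=None):
        if self.collect_events:
            self.log.append(
                {
                    "time": round(t, 6),
                    "patient": patient,
                    "event": event,
                    "station": station,
                    "resources": resources or {},
                }
            )

    # -- health dynamics --------------------------------------------------

    def _deteriorating(self, p: Patient) -> bool:
        return (
            p.state == "waiting"
            and p.first_treatment_start is None
            and self.cal.health.rate_for(p.category) > 0
        )

    def _current_h(self, p: Patient, t: float) -> float:
        if self._deteriorating(p):
            rate = self.cal.health.rate_for(p.category)
            return max(0.0, p.h - rate * (t - p.h_anchor))
        return p.h

    def _freeze_health(self, p: Patient, t: float):
        """Materialize the lazily tracked score and cancel pending crossings."""
        p.h = self._current_h(p, t)
        p.h_anchor = t
        p.health_version += 1

    def _schedule_health(self, p: Patient):
        """Schedule the patient's next downward threshold crossing exactly."""
        if not self._deteriorating(p):
            return
        dyn = self.cal.health
        rate = dyn.rate_for(p.category)
        target = {GREEN: dyn.theta_yellow, YELLOW: dyn.theta_red, RED: 0.0}[p.category]
        if p.h <= target:  # already at the boundary; cross immediately
            t_cross = self.clock
        else:
            t_cross = p.h_anchor + (p.h - target) / rate
        self._push(t_cross, "health", (p.id, p.health_version, target))

    def _on_health(self, payload):
        pid, version, target = payload
        p = self.patients[pid]
        if version != p.health_version or not self._deteriorating(p):
            return  # stale crossing
        p.h = target
        p.h_anchor = self.clock
        p.health_version += 1
        if target == 0.0:
            self._die(p)
            return
        down = {self.cal.health.theta_yellow: YELLOW, self.cal.health.theta_red: RED}
        old = p.category
        p.category = down[target]
        p.n_retriage += 1
        self._log(self.clock, p.id, "retriage", None, {"from": old, "to": p.category})
        self._requeue_after_retriage(p, old)
        self._schedule_health(p)

    def _die(self, p: Patient):
        p.category = BLACK
        p.state = "dead"
        p.death_time = self.clock
        p.queue_token = None  # queue entries become stale
        self.deaths += 1
        self.n_unsettled -= 1
        self._log(self.clock, p.id, "death")

    def _requeue_after_retriage(self, p: Patient, old_category: str):
        """A waiting patient whose category changed joins the queue that the
        new category's pathway prescribes, at the current time."""
        if p.queue_token is None:
            return
        station = p.queue_token[0]
        p.queue_token = None  # invalidate old entry
        if station == "triage":
            self._enqueue("triage", p)
        elif station in ("yellow_exam", "resus"):
            # pre-treatment station switches with the pathway
            self._enqueue("resus" if p.category == RED else "yellow_exam", p)
        else:
            self._enqueue(station, p)

    # -- queueing and resource grants -------------------------------------

    def _requirement(self, station: str, p: Patient) -> TaskRequirement:
        staffing = self.cal.staffing
        if station == "triage":
            return TaskRequirement("triage", _slots(staffing["triage"]), (), "triage")
        if station == "resus":
            return TaskRequirement("resus", _slots(staffing["red_stabilization"]), ("resus_bay",), "red_stabilization")
        if station == "yellow_exam":
            return TaskRequirement("yellow_exam", _slots(staffing["yellow_exam"]), ("yellow_slot",), "yellow_exam")
        if station == "ct":
            return TaskRequirement("ct", _slots(staffing["ct"]), ("ct_machine",), "ct")
        if station == "xray":
            return TaskRequirement("xray", _slots(staffing["xray"]), ("xray_machine",), "xray")
        if station == "surgery":
            if p.category == RED:
                return TaskRequirement("surgery", _slots(staffing["red_surgery"]), ("trauma_or", "central_or"), "red_surgery")
            return TaskRequirement("surgery", _slots(staffing["yellow_surgery"]), ("central_or", "trauma_or"), "yellow_surgery")
        raise ValueError(f"unknown station {station!r}")

    def _enqueue(self, station: str, p: Patient):
        self._seq += 1
        entry = (_PRIORITY[p.category], self.clock, self._seq, p.id)
        p.queue_token = (station, self._seq)
        p.state = "waiting"
        heapq.heappush(self.queues[station], entry)
        self._log(self.clock, p.id, "queue", station)

    def _try_seize(self, req: TaskRequirement) -> tuple[dict[str, int], str | None] | None:
        """Check simultaneous availability; return the allocation or None."""
        alloc: dict[str, int] = defaultdict(int)
        for slot in req.staff_slots:
            for cat in slot:
                if self.pools[cat].available() - alloc[cat] > 0:
                    alloc[cat] += 1
                    break
            else:
                return None
        room = None
        if req.room_options:
            for r in req.room_options:
                if self.pools[r].free() > 0:
                    room = r
                    break
            else:
                return None
        return dict(alloc), room

    def _allocate(self):
        """Grant queued tasks while resources allow, honoring priority order
        and first-come-first-served within each triage category."""
        progress = True
        while progress:
            progress = False
            for station in STATION_ORDER:
                q = self.queues[station]
                while q:
                    prio, enq_t, seq, pid = q[0]
                    p = self.patients[pid]
                    if p.queue_token != (station, seq):
                        heapq.heappop(q)  # stale (re-triaged, dead, or granted)
                        continue
                    got = self._try_seize(self._requirement(station, p))
                    if got is None:
                        break  # head-of-line blocking preserves FCFS fairness
                    heapq.heappop(q)
                    self._start_service(station, p, *got)
                    progress = True

    def _start_service(self, station: str, p: Patient, staff_alloc: dict[str, int], room: str | None):
        t = self.clock
        p.queue_token = None
        self._freeze_health(p, t)
        p.state = "in_service"
        req = self._requirement(station, p)
        resources = dict(staff_alloc)
        if room:
            resources[room] = 1
        for name, n in resources.items():
            self.pools[name].change_busy(t, +n)
        if station in ("resus", "yellow_exam") and p.first_treatment_start is None:
            p.first_treatment_start = t
            p.category_at_first_treatment = p.category
        if station == "surgery":
            p.surgery_start = t
            p.category_at_surgery = p.category
        dur = p.durations[req.service_key]
        self._log(t, p.id, "seize", station, resources)
        self._push(t + dur, "end", (p.id, station, tuple(sorted(resources.items())), dur))

    # -- event handlers ---------------------------------------------------

    def _on_arrival(self, pid: int):
        p = self.patients[pid]
        p.state = "waiting"
        p.h_anchor = self.clock
        self._log(self.clock, p.id, "arrive", None, {"category": p.category})
        if self.cal.triage_enabled:
            self._enqueue("triage", p)
        else:
            p.triage_done = True
            self._route(p)
        self._schedule_health(p)

    def _on_end(self, payload):
        pid, station, resources, dur = payload
        p = self.patients[pid]
        t = self.clock
        for name, n in resources:
            self.pools[name].change_busy(t, -n)
        self._log(t, p.id, "release", station, dict(resources))
        if station in _TREATMENT_STATIONS:
            update_health(p, dur, waiting=False, dynamics=self.cal.health)
            new_cat = retriage(p.h, self.cal.health)
            if _PRIORITY.get(new_cat, 3) > _PRIORITY[p.category]:  # improvement only
                self._log(t, p.id, "retriage", None, {"from": p.category, "to": new_cat})
                p.category = new_cat
                p.n_retriage += 1
        if station == "triage":
            p.triage_done = True
            self._log(t, p.id, "triage", None, {"category": p.category})
        elif station in ("ct", "xray"):
            p.imaged = True
        p.state = "waiting"
        p.h_anchor = t
        self._route(p)
        self._schedule_health(p)

    def _on_transfer_end(self, pid: int):
        p = self.patients[pid]
        p.transfer_done = True
        self._log(self.clock, p.id, "release", "transfer")
        p.state = "waiting"
        self._route(p)

    def _route(self, p: Patient):
        """Decide the patient's next task from their category and progress."""
        t = self.clock
        if not p.triage_done:
            self._enqueue("triage", p)
            return
        if p.category == GREEN and p.first_treatment_start is None:
            # slightly injured: gathered in the dining hall awaiting discharge
            p.state = "in_hall"
            self.n_hall += 1
            self._hall.append(p)
            self.n_unsettled -= 1
            self._update_supervision()
            self._log(t, p.id, "queue", "dining_hall")
            return
        if p.first_treatment_start is None:
            self._enqueue("resus" if p.category == RED else "yellow_exam", p)
            return
        if p.needs_imaging and not p.imaged:
            station = "xray"
            if p.ct_indicated:
                station = "ct"
                if p.downgrade_eligible and self.pools["ct_machine"].free() == 0:
                    station = "xray"  # switch to the more readily available X-ray
            p.imaging_station = station
            self._enqueue(station, p)
            return
        if p.needs_surgery and p.surgery_start is None and p.category != GREEN:
            self._enqueue("surgery", p)
            return
        if not p.transfer_done:
            p.state = "in_service"
            self._log(t, p.id, "seize", "transfer")
            self._push(t + p.durations["transfer"], "transfer_end", p.id)
            return
        p.state = "exited"
        p.exit_time = t
        self.n_unsettled -= 1
        self._log(t, p.id, "exit")

    def _update_supervision(self):
        nurses, rot = required_green_supervision(
            self.n_hall, self.cal.greens_per_nurse, self.cal.greens_per_rotation_physician
        )
        # supervision never absorbs the last unit of a category: clinical
        # tasks (triage above all) must stay structurally feasible
        npool, rpool = self.pools["general_nurses"], self.pools["rotation_physicians"]
        npool.set_reserved(self.clock, min(nurses, max(0, npool.capacity - 1)))
        rpool.set_reserved(self.clock, min(rot, max(0, rpool.capacity - 1)))

    def _on_routine_arrival(self):
        pool = self.pools["central_or"]
        if pool.free() > 0:
            dur = self.cal.service["routine_or_case"].sample(self.streams["routine"])
            pool.change_busy(self.clock, +1)
            self._routine_active += 1
            self._push(self.clock + dur, "routine_end", None)
            self._log(self.clock, None, "seize", "routine_or", {"central_or": 1})
        # an elective case arriving to a fully occupied theatre is postponed
        self._schedule_next_routine(self.clock)

    # -- main loop ---------------------------------------------------------

    def run(self) -> ReplicationResult:
        while self.heap:
            if self.n_unsettled == 0:
                break
            t, seq, kind, payload = heapq.heappop(self.heap)
            self._events_processed += 1
            if self._events_processed > self.max_events:
                raise RuntimeError(
                    f"event cap {self.max_events} exceeded at t={t:.1f}: likely a modeling bug (deadlock or runaway process)"
                )
            self.clock = t
            if kind == "arrival":
                self._on_arrival(payload)
            elif kind == "end":
                self._on_end(payload)
            elif kind == "transfer_end":
                self._on_transfer_end(payload)
            elif kind == "health":
                self._on_health(payload)
            elif kind == "routine_arrival":
                self._on_routine_arrival()
            elif kind == "routine_end":
                self.pools["central_or"].change_busy(t, -1)
                self._routine_active -= 1
                self._log(t, None, "release", "routine_or", {"central_or": 1})
            self._allocate()
        if self.n_unsettled != 0:
            raise RuntimeError("event calendar exhausted with patients still in the system")
        # discharge the dining hall at the horizon
        for p in self._hall:
            p.state = "exited"
            p.exit_time = self.clock
            self._log(self.clock, p.id, "exit")
        self.n_hall = 0
        self._update_supervision()
        # routine cases still running when the incident response ends are
        # handed back to normal operations
        while self._routine_active > 0:
            self.pools["central_or"].change_busy(self.clock, -1)
            self._routine_active -= 1
            self._log(self.clock, None, "release", "routine_or", {"central_or": 1})
        return self._result()

    def _result(self) -> ReplicationResult:
        end = self.clock
        makespan = max(end - self.t0, 1e-12)
        utilization = {}
        staff_workload = {}
        for name, pool in self.pools.items():
            pool._advance(end)
            if pool.capacity > 0:
                frac = pool.busy_time / (pool.capacity * makespan)
                if name in STAFF_CATEGORIES:
                    staff_workload[name] = frac
                else:
                    utilization[name] = frac
        records = [
            PatientRecord(
                patient_id=p.id,
                initial_category=p.initial_category,
                final_category=p.category,
                arrival=p.arrival,
                first_treatment_start=p.first_treatment_start,
                category_at_first_treatment=p.category_at_first_treatment,
                surgery_start=p.surgery_start,
                category_at_surgery=p.category_at_surgery,
                needs_surgery=p.needs_surgery,
                exit_time=p.exit_time,
                death_time=p.death_time,
                terminal="DECEASED" if p.death_time is not None else "EXITED",
                h_final=p.h,
                n_retriage=p.n_retriage,
            )
            for p in self.patients
        ]
        return ReplicationResult(
            records=records,
            utilization=utilization,
            staff_workload=staff_workload,
            deaths=self.deaths,
            end_time=end,
            start_time=self.t0,
            events=self.log if self.collect_events else None,
        )


def _slots(matrix) -> tuple[tuple[str, ...], ...]:
    return tuple(tuple(slot) for slot in matrix)


def run_replication(scenario: ScenarioConfig, seed, collect_events: bool = True, max_events: int | None = None) -> ReplicationResult:
    """Run one replication; identical (scenario, seed) pairs produce
    identical event logs and records."""
    return Simulation(scenario, seed, collect_events=collect_events, max_events=max_events).run()
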