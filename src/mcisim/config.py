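"""Scenario configuration for hospital mass-casualty-incident simulations.

A scenario bundles the casualty load (patients per triage category and the
window over which they arrive), the staff on shift (seven categories), the
structural resources of the trauma pathway (resuscitation bays, operating
rooms, imaging machines, outpatient treatment slots), and a calibration of
service-time distributions and health-score dynamics.  All times are minutes;
time of day is minutes since midnight.

The shipped calibration is a documented fixture: the hospital whose disaster
plan motivated this model did not publish its service durations, so the
defaults here are chosen from the literature-typical ranges and exposed for
replacement via JSON calibration files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Any

__all__ = [
    "STAFF_CATEGORIES",
    "StaffVector",
    "PatientLoad",
    "ResourceSet",
    "ServiceTime",
    "HealthDynamics",
    "Calibration",
    "ScenarioConfig",
    "default_calibration",
    "make_disaster_plan_baseline",
    "make_optimization_baseline",
    "minimum_staff_vector",
    "maximum_staff_vector",
    "scale_load",
    "validate_config",
    "load_config",
    "save_config",
    "load_sweep_fixture_rows",
]

#: The seven staff categories modeled as potentially scarce, in canonical order.
STAFF_CATEGORIES = (
    "medical_specialists",
    "medical_assistants",
    "rotation_physicians",
    "general_nurses",
    "surgical_assistants",
    "surgical_nurses",
    "radiology_assistants",
)


@dataclass(frozen=True)
class StaffVector:
    """Headcount on shift per staff category (non-negative integers)."""

    medical_specialists: int
    medical_assistants: int
    rotation_physicians: int
    general_nurses: int
    surgical_assistants: int
    surgical_nurses: int
    radiology_assistants: int

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(getattr(self, c) for c in STAFF_CATEGORIES)

    def as_dict(self) -> dict[str, int]:
        return {c: getattr(self, c) for c in STAFF_CATEGORIES}

    @property
    def total(self) -> int:
        return sum(self.as_tuple())

    @classmethod
    def from_tuple(cls, values) -> "StaffVector":
        values = tuple(int(v) for v in values)
        if len(values) != len(STAFF_CATEGORIES):
            raise ValueError(f"staff vector needs {len(STAFF_CATEGORIES)} components, got {len(values)}")
        return cls(*values)

    def replace(self, **kwargs) -> "StaffVector":
        return dataclasses.replace(self, **kwargs)

    def __ge__(self, other: "StaffVector") -> bool:
        return all(a >= b for a, b in zip(self.as_tuple(), other.as_tuple()))


@dataclass(frozen=True)
class PatientLoad:
    """Casualty counts per triage category and their arrival window.

    ``arrival_window_min`` is the expected makespan of the arrival process:
    within each category inter-arrival times are exponential with mean
    ``window / n`` (see :mod:`mcisim.engine`).
    """

    n_red: int
    n_yellow: int
    n_green: int
    arrival_window_min: float = 90.0
    incident_time_of_day: float = 1320.0  # 10 p.m.

    def counts(self) -> tuple[int, int, int]:
        return (self.n_red, self.n_yellow, self.n_green)


#: Sentinel for an effectively unbounded room (the dining hall).
UNBOUNDED = None


@dataclass(frozen=True)
class ResourceSet:
    """Structural resources of the trauma pathway.

    Two operating rooms are reserved exclusively for trauma surgery; of the
    five central operating rooms only four are generally usable due to
    staffing.  The second resuscitation bay is an improvised one in the
    procedures room.  Yellow treatment slots pool the acute outpatient
    department and the cast room.
    """

    n_trauma_or: int = 2
    n_central_or_usable: int = 4
    n_resus_bays: int = 2
    n_ct: int = 1
    n_xray: int = 2
    n_yellow_treatment_slots: int = 4
    dining_hall_capacity: int | None = UNBOUNDED


@dataclass(frozen=True)
class ServiceTime:
    """A named service-time distribution (minutes).

    families: ``lognormal`` (parameterized by mean and coefficient of
    variation), ``exponential`` (mean), ``fixed`` (constant).
    """

    family: str
    mean: float
    cv: float = 0.35

    def __post_init__(self):
        if self.family not in ("lognormal", "exponential", "fixed"):
            raise ValueError(f"unknown service-time family {self.family!r}")
        if self.mean < 0:
            raise ValueError("service-time mean must be non-negative")

    def sample(self, rng, size=None):
        """Draw durations; always non-negative."""
        import numpy as np

        if self.family == "fixed" or self.mean == 0:
            return np.full(size, self.mean) if size is not None else self.mean
        if self.family == "exponential":
            return rng.exponential(self.mean, size=size)
        # lognormal with given mean and cv
        s2 = math.log(1.0 + self.cv**2)
        mu = math.log(self.mean) - 0.5 * s2
        return rng.lognormal(mu, math.sqrt(s2), size=size)


@dataclass(frozen=True)
class HealthDynamics:
    """Health-score dynamics on the 0..99 scale.

    While a patient awaits their first clinical treatment the score falls at
    the category's deterioration rate (points/min); during treatment it rises
    at ``r_improve``.  Crossing ``theta_red``/``theta_yellow`` re-triages the
    patient (progressive patient care); 0 is death (absorbing, black).
    """

    d_red: float = 0.25
    d_yellow: float = 0.05
    d_green: float = 0.0
    r_improve: float = 0.5
    theta_red: float = 30.0
    theta_yellow: float = 70.0

    def rate_for(self, category: str) -> float:
        return {"red": self.d_red, "yellow": self.d_yellow, "green": self.d_green}[category]


_DEFAULT_SERVICE = {
    "triage": ServiceTime("lognormal", 2.0),
    "red_stabilization": ServiceTime("lognormal", 25.0),
    "yellow_exam": ServiceTime("lognormal", 20.0),
    "ct": ServiceTime("lognormal", 15.0),
    "xray": ServiceTime("lognormal", 8.0),
    "red_surgery": ServiceTime("lognormal", 90.0),
    "yellow_surgery": ServiceTime("lognormal", 60.0),
    "transfer": ServiceTime("lognormal", 20.0),
    "routine_or_case": ServiceTime("lognormal", 60.0, 0.5),
}

# Task staffing matrices: per station, a sequence of slots; each slot lists the
# staff categories that may fill it, in order of preference.
_DEFAULT_STAFFING = {
    "triage": [["rotation_physicians"], ["general_nurses"]],
    "red_stabilization": [
        ["medical_specialists"],
        ["medical_assistants"],
        ["surgical_assistants"],
        ["general_nurses"],
    ],
    "yellow_exam": [["medical_assistants", "rotation_physicians"], ["general_nurses"]],
    "red_surgery": [
        ["medical_specialists"],
        ["medical_specialists"],
        ["surgical_nurses"],
        ["surgical_assistants"],
    ],
    "yellow_surgery": [["medical_specialists"], ["surgical_nurses"]],
    "ct": [["radiology_assistants"]],
    "xray": [["radiology_assistants"]],
    "transfer": [],
}


@dataclass(frozen=True)
class Calibration:
    """Service-time distributions, health dynamics, and pathway probabilities.

    All probability fields are per-patient Bernoulli parameters.  The staffing
    matrices (which staff categories a task seizes) live here, not in code, so
    hospitals with different task compositions can be modeled from a JSON
    calibration file alone.
    """

    service: dict[str, ServiceTime] = field(default_factory=lambda: dict(_DEFAULT_SERVICE))
    health: HealthDynamics = field(default_factory=HealthDynamics)
    staffing: dict[str, list[list[str]]] = field(
        default_factory=lambda: {k: [list(s) for s in v] for k, v in _DEFAULT_STAFFING.items()}
    )
    # initial health-score ranges (uniform), consistent with the thresholds
    init_health: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"red": (12.0, 28.0), "yellow": (35.0, 69.0), "green": (75.0, 99.0)}
    )
    p_red_surgery: float = 1.0
    p_yellow_surgery: float = 0.4
    p_imaging_red: float = 1.0
    p_imaging_yellow: float = 1.0
    p_ct_red: float = 0.9  # else X-ray
    p_ct_yellow: float = 0.2
    p_ct_downgrade_eligible: float = 0.5
    # background (routine) operating-room workload, cases per hour
    routine_day_rate_per_h: float = 1.5
    routine_night_rate_per_h: float = 0.2
    routine_day_start: float = 420.0  # 7:00
    routine_day_end: float = 1020.0  # 17:00
    # ratios for supervising slightly injured patients in the dining hall
    greens_per_nurse: int = 10
    greens_per_rotation_physician: int = 25
    triage_enabled: bool = True

    def service_mean(self, key: str) -> float:
        return self.service[key].mean


@dataclass(frozen=True)
class PrecisionSpec:
    """Sequential replication control: stop when the t-based confidence
    interval of the running mean is within ``rel_halfwidth`` of its value."""

    confidence: float = 0.95
    rel_halfwidth: float = 0.05
    pilot: int = 10
    max_replications: int = 20000


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one policy scenario."""

    label: str
    staff: StaffVector
    load: PatientLoad
    resources: ResourceSet = field(default_factory=ResourceSet)
    calibration: Calibration = field(default_factory=Calibration)
    seed: int = 0
    replications: int = 200
    precision: PrecisionSpec | None = None

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)


def default_calibration() -> Calibration:
    return Calibration()


def make_disaster_plan_baseline(seed: int = 0) -> ScenarioConfig:
    """Baseline scenario #1: the hospital's current disaster plan.

    5 severely, 20 moderately and 50 slightly injured patients arriving
    within 90 minutes at 10 p.m., with the night-shift staff mix
    (17, 5, 3, 20, 1, 4, 2).
    """
    return ScenarioConfig(
        label="disaster-plan-baseline",
        staff=StaffVector(17, 5, 3, 20, 1, 4, 2),
        load=PatientLoad(5, 20, 50, arrival_window_min=90.0, incident_time_of_day=1320.0),
        seed=seed,
    )


def make_optimization_baseline(seed: int = 0) -> ScenarioConfig:
    """Baseline scenario #2 used by the staff-mix optimization study:
    same casualty load as baseline #1, staff (11, 5, 6, 23, 2, 5, 2)."""
    return make_disaster_plan_baseline(seed=seed).replace(
        label="optimization-baseline",
        staff=StaffVector(11, 5, 6, 23, 2, 5, 2),
    )


def minimum_staff_vector() -> StaffVector:
    """Lower corner of the staff-mix search lattice."""
    return StaffVector(8, 3, 4, 15, 1, 4, 1)


def maximum_staff_vector() -> StaffVector:
    """Upper corner of the staff-mix search lattice."""
    return StaffVector(12, 7, 8, 25, 3, 8, 3)


def scale_load(load: PatientLoad, factor: float, overrides: dict[str, int] | None = None) -> PatientLoad:
    """Scale casualty counts by ``factor`` with round-half-up per category.

    ``overrides`` replaces individual category counts after scaling, because
    published sweep tables occasionally deviate from any uniform rounding
    rule and must be reproducible verbatim.
    """
    if factor <= 0:
        raise ValueError("scale factor must be positive")

    def _round_half_up(x: float) -> int:
        return int(math.floor(x + 0.5))

    counts = {
        "n_red": _round_half_up(load.n_red * factor),
        "n_yellow": _round_half_up(load.n_yellow * factor),
        "n_green": _round_half_up(load.n_green * factor),
    }
    if overrides:
        unknown = set(overrides) - set(counts)
        if unknown:
            raise ValueError(f"unknown load override(s): {sorted(unknown)}")
        counts.update({k: int(v) for k, v in overrides.items()})
    return dataclasses.replace(load, **counts)


def load_sweep_fixture_rows() -> list[PatientLoad]:
    """The casualty-load sweep rows (scenarios #5..#9 analog) as printed in
    the source study's load table, including its non-uniform +40% row."""
    base = make_disaster_plan_baseline().load
    return [
        scale_load(base, 0.4),  # (2, 8, 20)
        scale_load(base, 0.6),  # (3, 12, 30)
        scale_load(base, 0.8),  # (4, 16, 40)
        scale_load(base, 1.2),  # (6, 24, 60)
        scale_load(base, 1.4, overrides={"n_yellow": 29, "n_green": 72}),  # (7, 29, 72)
    ]


def validate_config(cfg: ScenarioConfig) -> list[str]:
    """Return a list of human-readable invariant violations (empty iff valid)."""
    v: list[str] = []
    for cat in STAFF_CATEGORIES:
        if getattr(cfg.staff, cat) < 0:
            v.append(f"staff.{cat}: negative headcount")
    for name in ("n_red", "n_yellow", "n_green"):
        if getattr(cfg.load, name) < 0:
            v.append(f"load.{name}: negative count")
    if cfg.load.arrival_window_min <= 0:
        v.append("load.arrival_window_min: must be positive")
    if not (0 <= cfg.load.incident_time_of_day < 1440):
        v.append("load.incident_time_of_day: must be in [0, 1440)")
    for name in (
        "n_trauma_or",
        "n_central_or_usable",
        "n_resus_bays",
        "n_ct",
        "n_xray",
        "n_yellow_treatment_slots",
    ):
        if getattr(cfg.resources, name) < 0:
            v.append(f"resources.{name}: negative count")
    if cfg.load.n_red > 0 and cfg.resources.n_resus_bays < 1:
        v.append("resources.n_resus_bays: at least one bay required when severely injured patients arrive")
    if cfg.load.n_red > 0 and cfg.resources.n_trauma_or + cfg.resources.n_central_or_usable < 1:
        v.append("resources: no operating room available for surgical patients")

    cal = cfg.calibration
    for pname in (
        "p_red_surgery",
        "p_yellow_surgery",
        "p_imaging_red",
        "p_imaging_yellow",
        "p_ct_red",
        "p_ct_yellow",
        "p_ct_downgrade_eligible",
    ):
        p = getattr(cal, pname)
        if not (0.0 <= p <= 1.0):
            v.append(f"calibration.{pname}: probability outside [0, 1]")
    h = cal.health
    if not (h.d_red >= h.d_yellow >= h.d_green >= 0):
        v.append("calibration.health: deterioration rates must satisfy d_red >= d_yellow >= d_green >= 0")
    if not (0 < h.theta_red < h.theta_yellow < 99):
        v.append("calibration.health: thresholds must satisfy 0 < theta_red < theta_yellow < 99")
    for key, st in cal.service.items():
        if st.mean < 0:
            v.append(f"calibration.service.{key}: negative mean")

    # structural staffing feasibility: every slot of every potentially used
    # task must have at least one fillable option
    used = set()
    if cal.triage_enabled and (cfg.load.n_red or cfg.load.n_yellow or cfg.load.n_green):
        used.add("triage")
    red_pathway = cfg.load.n_red > 0 or (cfg.load.n_yellow > 0 and cal.health.d_yellow > 0)
    if red_pathway:  # yellows may be re-triaged red while waiting
        used.update({"red_stabilization", "transfer"})
        if cal.p_red_surgery > 0:
            used.add("red_surgery")
        if cal.p_imaging_red > 0:
            used.add("xray")
            if cal.p_ct_red > 0:
                used.add("ct")
    if cfg.load.n_yellow:
        used.update({"yellow_exam", "transfer"})
        if cal.p_yellow_surgery > 0:
            used.add("yellow_surgery")
        if cal.p_imaging_yellow > 0:
            used.add("xray")
            if cal.p_ct_yellow > 0:
                used.add("ct")
    for station in sorted(used):
        for slot in cal.staffing.get(station, []):
            if slot and all(getattr(cfg.staff, c, 0) == 0 for c in slot):
                v.append(f"staffing.{station}: slot {slot} has no staff available (structurally infeasible)")

    return v


# ---------------------------------------------------------------------------
# JSON serialization


def _config_to_dict(cfg: ScenarioConfig) -> dict[str, Any]:
    d = dataclasses.asdict(cfg)
    return d


def _calibration_from_dict(d: dict[str, Any]) -> Calibration:
    service = {k: ServiceTime(**v) for k, v in d.get("service", {}).items()}
    health = HealthDynamics(**d.get("health", {}))
    kwargs = {
        k: v
        for k, v in d.items()
        if k not in ("service", "health", "init_health", "staffing")
    }
    init_health = {k: tuple(v) for k, v in d.get("init_health", {}).items()}
    cal = Calibration(
        service=service or dict(_DEFAULT_SERVICE),
        health=health,
        staffing=d.get("staffing") or {k: [list(s) for s in v] for k, v in _DEFAULT_STAFFING.items()},
        init_health=init_health or Calibration().init_health,
        **kwargs,
    )
    return cal


def config_from_dict(d: dict[str, Any]) -> ScenarioConfig:
    staff = StaffVector(**d["staff"])
    load = PatientLoad(**d["load"])
    resources = ResourceSet(**d.get("resources", {}))
    calibration = _calibration_from_dict(d.get("calibration", {}))
    precision = PrecisionSpec(**d["precision"]) if d.get("precision") else None
    return ScenarioConfig(
        label=d.get("label", "scenario"),
        staff=staff,
        load=load,
        resources=resources,
        calibration=calibration,
        seed=int(d.get("seed", 0)),
        replications=int(d.get("replications", 200)),
        precision=precision,
    )


def save_config(cfg: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(_config_to_dict(cfg), fh, indent=2)
        fh.write("\n")


def load_config(path) -> ScenarioConfig:
    """Read a scenario config from JSON and validate it.

    Raises ``ValueError`` naming the offending field on schema violations.
    """
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValueError(f"config {path}: not valid JSON ({e})") from e
    cfg = config_from_dict(d)
    violations = validate_config(cfg)
    if violations:
        raise ValueError(f"config {path}: " + "; ".join(violations))
    return cfg
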