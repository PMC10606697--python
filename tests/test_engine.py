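"""Event engine: arrivals, health dynamics, routing, priority, invariants."""

import dataclasses
import math

import numpy as np
import pytest

import mcisim
from mcisim import HealthDynamics, PatientLoad, ResourceSet, ServiceTime, StaffVector
from mcisim.engine import Patient, generate_arrivals, required_green_supervision, retriage, update_health

from conftest import replay_capacity_safety, replay_conservation, replay_priority_honor

DYN = HealthDynamics()


def _patient(category="red", h=50.0):
    return Patient(0, category, h, 0.0, True, True, False, False, {})


class TestHealthDynamics:
    def test_zero_rate_is_identity(self):
        p = _patient("green", 80.0)
        update_health(p, 500.0, waiting=True, dynamics=DYN)
        assert p.h == 80.0

    def test_deterioration_to_death_is_absorbing(self):
        p = _patient("red", 10.0)
        update_health(p, 20.0, waiting=True, dynamics=HealthDynamics(d_red=0.5))
        assert p.h == 0.0 and p.category == "black"
        with pytest.raises(ValueError):
            update_health(p, 1.0, waiting=True, dynamics=DYN)

    def test_improvement_clamps_at_perfect_health(self):
        p = _patient("yellow", 95.0)
        update_health(p, 10.0, waiting=False, dynamics=HealthDynamics(r_improve=1.0))
        assert p.h == 99.0

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            update_health(_patient(), -1.0, waiting=True, dynamics=DYN)

    @pytest.mark.parametrize(
        "h, expected",
        [(0.0, "black"), (1.0, "red"), (29.9, "red"), (30.0, "yellow"), (69.9, "yellow"), (70.0, "green"), (99.0, "green")],
    )
    def test_retriage_thresholds(self, h, expected):
        assert retriage(h, DYN) == expected

    def test_retriage_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            retriage(100.0, DYN)
        with pytest.raises(ValueError):
            retriage(-1.0, DYN)


class TestGreenSupervision:
    @pytest.mark.parametrize("n, expected", [(50, (5, 2)), (0, (0, 0)), (26, (3, 2)), (1, (1, 1)), (25, (3, 1))])
    def test_ceiling_ratios(self, n, expected):
        assert required_green_supervision(n) == expected


class TestArrivals:
    def test_counts_and_empty_category(self):
        rng = np.random.default_rng(0)
        events = generate_arrivals(PatientLoad(5, 0, 50, 90.0, 0.0), rng)
        cats = [c for _, c in events]
        assert cats.count("red") == 5 and cats.count("yellow") == 0 and cats.count("green") == 50
        assert all(t2 >= t1 for (t1, _), (t2, _) in zip(events, events[1:]))

    def test_expected_makespan_matches_window(self):
        # the sum of n exponential gaps of mean window/n has mean = window
        rng = np.random.default_rng(1)
        load = PatientLoad(5, 0, 0, 90.0, 0.0)
        makespans = []
        for _ in range(10_000):
            events = generate_arrivals(load, rng)
            makespans.append(events[-1][0])
        se = 90.0 / math.sqrt(5) / math.sqrt(10_000)
        assert abs(np.mean(makespans) - 90.0) < 3 * se


class TestReproducibilityAndInvariants:
    def test_same_seed_identical_event_logs(self, baseline):
        a = mcisim.run_replication(baseline, 99, collect_events=True)
        b = mcisim.run_replication(baseline, 99, collect_events=True)
        assert a.events == b.events
        assert [r.exit_time for r in a.records] == [r.exit_time for r in b.records]

    def test_engine_invariants_on_baseline_log(self, baseline, baseline_result):
        replay_capacity_safety(baseline, baseline_result.events)
        replay_priority_honor(baseline_result.events)
        replay_conservation(baseline, baseline_result.events, baseline_result.records)

    def test_utilizations_are_fractions(self, baseline_result):
        for v in {**baseline_result.utilization, **baseline_result.staff_workload}.values():
            assert 0.0 <= v <= 1.0


class TestRouting:
    def test_zero_queue_oracle(self):
        """With effectively infinite resources and no deterioration, every
        queue wait is zero and system time is the sum of service times."""
        cal = dataclasses.replace(
            mcisim.default_calibration(),
            health=HealthDynamics(0.0, 0.0, 0.0, 0.5, 30.0, 70.0),
            routine_day_rate_per_h=0.0,
            routine_night_rate_per_h=0.0,
        )
        cfg = mcisim.make_disaster_plan_baseline().replace(
            staff=StaffVector(99, 99, 99, 99, 99, 99, 99),
            resources=ResourceSet(99, 99, 99, 99, 99, 99, None),
            calibration=cal,
        )
        res = mcisim.run_replication(cfg, 5, collect_events=True)
        pending = {}
        service = {}
        for e in res.events:
            pid = e["patient"]
            if e["event"] == "queue" and e["station"] != "dining_hall":
                pending[(pid, e["station"])] = e["time"]
            elif e["event"] == "seize" and pid is not None:
                key = (pid, e["station"])
                if key in pending:
                    assert e["time"] == pytest.approx(pending.pop(key), abs=1e-9)
                service.setdefault(pid, []).append(e["time"])
            elif e["event"] == "release" and pid is not None:
                service[pid].append(-e["time"])
        assert not pending
        for r in res.records:
            if r.initial_category == "green" or r.exit_time is None:
                continue
            total_service = -sum(service[r.patient_id])
            assert mcisim.total_system_time(r) == pytest.approx(total_service, abs=1e-6)

    def test_yellow_upgraded_to_red_joins_red_pathway(self):
        """A moderately injured patient deteriorating past the red threshold
        while queued is re-queued on the red pathway at the current time."""
        cal = dataclasses.replace(
            mcisim.default_calibration(),
            health=HealthDynamics(d_red=0.5, d_yellow=0.5, d_green=0.0, r_improve=0.5),
            init_health={"red": (12.0, 28.0), "yellow": (31.0, 33.0), "green": (75.0, 99.0)},
            service={**mcisim.default_calibration().service, "yellow_exam": ServiceTime("fixed", 60.0)},
            routine_day_rate_per_h=0.0,
            routine_night_rate_per_h=0.0,
        )
        cfg = mcisim.make_disaster_plan_baseline().replace(
            load=PatientLoad(0, 3, 0, arrival_window_min=5.0),
            resources=dataclasses.replace(ResourceSet(), n_yellow_treatment_slots=1),
            calibration=cal,
        )
        res = mcisim.run_replication(cfg, 2, collect_events=True)
        upgrades = [e for e in res.events if e["event"] == "retriage" and e["resources"] == {"from": "yellow", "to": "red"}]
        assert upgrades, "expected at least one yellow-to-red upgrade"
        pid = upgrades[0]["patient"]
        t_up = upgrades[0]["time"]
        requeues = [
            e for e in res.events
            if e["patient"] == pid and e["event"] == "queue" and e["station"] == "resus" and e["time"] == t_up
        ]
        assert requeues, "upgraded patient must re-queue for the resuscitation bay at the upgrade time"

    def test_ct_downgrade_to_xray_when_ct_busy(self):
        """Eligible CT-indicated patients switch to X-ray while every CT
        machine is occupied."""
        base = mcisim.make_disaster_plan_baseline()
        cal = dataclasses.replace(
            base.calibration,
            p_ct_red=1.0,
            p_ct_downgrade_eligible=1.0,
            p_red_surgery=0.0,
            service={**base.calibration.service, "ct": ServiceTime("fixed", 60.0)},
            routine_day_rate_per_h=0.0,
            routine_night_rate_per_h=0.0,
        )
        cfg = base.replace(
            load=PatientLoad(5, 0, 0, arrival_window_min=10.0),
            staff=StaffVector(20, 20, 20, 40, 10, 10, 10),
            calibration=cal,
        )
        res = mcisim.run_replication(cfg, 3, collect_events=True)
        ct = sum(1 for e in res.events if e["event"] == "seize" and e["station"] == "ct")
        xray = sum(1 for e in res.events if e["event"] == "seize" and e["station"] == "xray")
        assert ct >= 1 and xray >= 1 and ct + xray == 5

    def test_greens_gather_in_dining_hall_without_clinical_tasks(self):
        cfg = mcisim.make_disaster_plan_baseline().replace(load=PatientLoad(0, 0, 20, 30.0, 600.0))
        res = mcisim.run_replication(cfg, 4, collect_events=True)
        stations = {e["station"] for e in res.events if e["event"] == "seize" and e["patient"] is not None}
        assert stations <= {"triage"}
        assert sum(1 for e in res.events if e["station"] == "dining_hall") == 20
        assert all(r.exit_time is not None for r in res.records)


class TestRoutineWorkload:
    def test_zero_intensity_means_no_background_cases(self, baseline):
        cal = dataclasses.replace(baseline.calibration, routine_day_rate_per_h=0.0, routine_night_rate_per_h=0.0)
        res = mcisim.run_replication(baseline.replace(calibration=cal), 1, collect_events=True)
        assert not any(e["station"] == "routine_or" for e in res.events)

    def test_ongoing_cases_at_night_match_thinning_oracle(self, baseline):
        """The expected number of routine cases already occupying a central
        operating room at the 10 p.m. incident equals the integral of the
        arrival intensity times the duration survival function."""
        from scipy import integrate, stats

        cal = baseline.calibration
        t0 = baseline.load.incident_time_of_day
        st_ = cal.service["routine_or_case"]
        s2 = math.log(1 + st_.cv**2)
        scale = math.exp(math.log(st_.mean) - 0.5 * s2)

        def rate(s):
            tod = s % 1440
            per_h = cal.routine_day_rate_per_h if cal.routine_day_start <= tod < cal.routine_day_end else cal.routine_night_rate_per_h
            return per_h / 60.0

        expected, _ = integrate.quad(lambda s: rate(s) * stats.lognorm.sf(t0 - s, math.sqrt(s2), scale=scale), t0 - 480, t0)
        counts = []
        for seed in range(300):
            res = mcisim.run_replication(baseline, seed, collect_events=True)
            counts.append(sum(1 for e in res.events if e["station"] == "routine_or" and e["event"] == "seize" and e["time"] == t0))
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se + 0.05  # small slack: finite lookback truncates the duration tail
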