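"""Shared fixtures and event-log replay checks.

The replay helpers re-derive engine invariants (resource-capacity safety,
seize/release pairing, triage-priority honor, patient conservation) from the
JSONL-style event log alone, independently of the engine's internal state.
"""

from __future__ import annotations

import pytest

import mcisim

_PRIORITY = {"red": 0, "yellow": 1, "green": 2}


@pytest.fixture(scope="session")
def baseline():
    return mcisim.make_disaster_plan_baseline()


@pytest.fixture(scope="session")
def baseline_result(baseline):
    return mcisim.run_replication(baseline, 12345, collect_events=True)


def replay_capacity_safety(scenario, events):
    """Occupancy per resource pool, reconstructed from seize/release events,
    never exceeds capacity; every seize is matched by a release."""
    caps = {c: getattr(scenario.staff, c) for c in mcisim.STAFF_CATEGORIES}
    r = scenario.resources
    caps.update(
        resus_bay=r.n_resus_bays,
        yellow_slot=r.n_yellow_treatment_slots,
        trauma_or=r.n_trauma_or,
        central_or=r.n_central_or_usable,
        ct_machine=r.n_ct,
        xray_machine=r.n_xray,
    )
    busy = {k: 0 for k in caps}
    open_seizes = 0
    for e in events:
        if e["event"] not in ("seize", "release"):
            continue
        sign = +1 if e["event"] == "seize" else -1
        open_seizes += sign
        for pool, n in e["resources"].items():
            if pool not in busy:
                continue
            busy[pool] += sign * n
            assert 0 <= busy[pool] <= caps[pool], f"{pool}: occupancy {busy[pool]} vs capacity {caps[pool]} at t={e['time']}"
    assert open_seizes == 0, "unmatched seize/release"
    assert all(v == 0 for v in busy.values()), "resources still held at the horizon"


def replay_priority_honor(events):
    """No yellow/green grant at a station while a red patient queued earlier
    for the same station is still waiting."""
    category = {}
    queued: dict[str, dict] = {}
    for e in events:
        pid = e["patient"]
        if e["event"] == "arrive":
            category[pid] = e["resources"]["category"]
        elif e["event"] == "retriage":
            category[pid] = e["resources"]["to"]
        elif e["event"] == "queue" and e["station"] != "dining_hall":
            for st in queued.values():  # at most one queue membership
                st.pop(pid, None)
            queued.setdefault(e["station"], {})[pid] = e["time"]
        elif e["event"] == "seize" and pid is not None:
            st = queued.get(e["station"], {})
            if pid in st:
                t_q = st.pop(pid)
                if _PRIORITY[category[pid]] > 0:
                    for other, t_o in st.items():
                        assert not (
                            category[other] == "red" and t_o <= t_q
                        ), f"{category[pid]} patient {pid} granted {e['station']} before red patient {other}"
        elif e["event"] == "death":
            for st in queued.values():
                st.pop(pid, None)


def replay_conservation(scenario, events, records):
    """Every casualty terminates exactly once (exit or death) and no event
    follows a patient's death."""
    n_total = sum(scenario.load.counts())
    exits = sum(1 for e in events if e["event"] == "exit")
    deaths = sum(1 for e in events if e["event"] == "death")
    assert exits + deaths == n_total
    assert len(records) == n_total
    dead_at = {}
    for e in events:
        pid = e["patient"]
        if pid is None:
            continue
        assert pid not in dead_at, f"event {e['event']} after death of patient {pid}"
        if e["event"] == "death":
            dead_at[pid] = e["time"]
    for r in records:
        assert (r.final_category == "black") == (r.death_time is not None) == (r.h_final == 0.0)
        assert 0.0 <= r.h_final <= 99.0
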