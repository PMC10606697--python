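"""Tabular and event-log output writers."""

from __future__ import annotations

import json

import pandas as pd

from .outcomes import Benchmarks, SummaryRow, pooled_critical_waits, summarize

__all__ = ["write_events_jsonl", "summary_table", "write_summary_csv"]


def write_events_jsonl(events, path) -> None:
    """One JSON object per line: time, patient id, event kind, station,
    resource ids."""
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps(ev) + "\n")


def summary_table(results, benchmarks: Benchmarks = Benchmarks()) -> pd.DataFrame:
    """Per-category critical-wait summary over patient-level values pooled
    across replications, with the applicable benchmark in a companion column
    (the layout of the published waiting-time tables)."""
    rows = []
    for cat in ("red", "yellow"):
        waits = pooled_critical_waits(results, cat)
        if not waits:
            continue
        row: SummaryRow = summarize(waits)
        rows.append({"metric": f"{cat}_critical_wait", **row.as_dict(), "benchmark": benchmarks.limit_for(cat)})
    deaths = [r.deaths for r in results]
    if deaths:
        rows.append({"metric": "deaths", **summarize(deaths).as_dict(), "benchmark": float("nan")})
    return pd.DataFrame(rows)


def write_summary_csv(results, path, benchmarks: Benchmarks = Benchmarks()) -> None:
    summary_table(results, benchmarks).to_csv(path, index=False)
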