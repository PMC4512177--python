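#!/usr/bin/env python
"""Summarize CR and UR timing from the demonstration cohort.

Reads the per-trial metrics written by 01_simulate_cohort.py and reports,
per group: CR onset latency, peak latency, and 10-90% rise time from the
CS-only probe trials of late acquisition, and UR latency/rise time from the
first training session, with an unpaired comparison of rise times.
"""

import sys
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

from eyeblink.pipeline import read_table, write_table
from eyeblink.stats import unpaired_t


def main() -> None:
    path = RESULTS / "trial_metrics.csv"
    if not path.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    trials = read_table(path, required=["subject_id", "group", "phase", "session", "kind", "status"])

    crs = trials[(trials.status == "cr") & (trials.phase == "acquisition") & (trials.session >= 8)]
    per_subj = crs.groupby(["group", "subject_id"])[
        ["onset_latency_ms", "peak_latency_ms", "rise_time_10_90_ms", "peak_amplitude"]
    ].mean().reset_index()
    print("late-acquisition CR timing (per-subject means):")
    summary = per_subj.groupby("group")[
        ["onset_latency_ms", "peak_latency_ms", "rise_time_10_90_ms", "peak_amplitude"]
    ].agg(["mean", "sem"])
    print(summary.round(1).to_string())

    groups = sorted(per_subj.group.unique())
    if len(groups) == 2:
        a = per_subj[per_subj.group == groups[0]]["rise_time_10_90_ms"].to_numpy()
        b = per_subj[per_subj.group == groups[1]]["rise_time_10_90_ms"].to_numpy()
        print(f"\nrise time {groups[0]} vs {groups[1]}: {unpaired_t(a, b).report()}")

    urs = trials[trials.status == "ur"]
    if not urs.empty:
        ur_sum = urs.groupby("group")[["ur_latency_ms", "ur_rise_time_ms"]].agg(["mean", "sem"])
        print("\nfirst-session UR metrics:")
        print(ur_sum.round(1).to_string())

    write_table(per_subj, RESULTS / "cr_timing_by_subject.csv")
    print(f"\nper-subject timing table: {RESULTS / 'cr_timing_by_subject.csv'}")


if __name__ == "__main__":
    sys.exit(main())
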