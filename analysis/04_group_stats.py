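#!/usr/bin/env python
"""Run the cohort-comparison battery on the demonstration cohort.

Reads results/session_metrics.csv and produces, per metric (probability,
amplitude, %CR): the last-four-session unpaired t-test with Cohen's d',
the age-covariate ANCOVA, and the mixed-design RM ANOVA (genotype between,
session within); plus the paired extinction and savings contrasts and the
learning-curve figure.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

from eyeblink.pipeline import compare_groups, format_report, read_table, render_report


def main() -> None:
    path = RESULTS / "session_metrics.csv"
    if not path.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    sess = read_table(
        path, required=["subject_id", "group", "phase", "session", "probability"]
    )
    results = compare_groups(sess)
    report = format_report(results)
    print(report)
    paths = render_report(sess, results, RESULTS)
    print("artifacts: " + ", ".join(str(p) for p in paths))


if __name__ == "__main__":
    sys.exit(main())
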