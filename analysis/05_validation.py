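#!/usr/bin/env python
"""Reduced-size Monte-Carlo validation of the estimators and tests.

A quicker rendition of the studies the acceptance suite runs in full:
decomposition null calibration and mixture recovery, CR/UR timing recovery,
type-I error of the group tests, and phenotype-detection power.  Results go
to results/validation.json.
"""

import json
import sys
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

from eyeblink import montecarlo as mc


def main() -> None:
    rng = np.random.default_rng(99)
    out = {}
    out["null_probability_10k"] = mc.null_probability(rng)
    rec = mc.mixture_recovery(seed=99, n_seeds=5)
    out["mixture_recovery_pass_rate"] = float(rec["ok"].mean())
    tim = mc.cr_timing_recovery(rng, n_trials=100)
    out["cr_timing"] = {k: round(v, 2) for k, v in tim.items()}
    out["ur_timing"] = {k: round(v, 2) for k, v in mc.ur_latency_recovery(rng, 50).items()}
    cal = mc.type1_calibration(rng, n_reps=300)
    out["type1_error"] = {k: v for k, v in cal.items()}
    out["probability_deficit_power_50"] = float(
        np.mean([mc.probability_deficit_replicate(rng) < 0.05 for _ in range(50)])
    )
    out["timing_deficit_power_25"] = float(
        np.mean([mc.timing_deficit_replicate(rng) < 0.05 for _ in range(25)])
    )
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "validation.json").write_text(json.dumps(out, indent=2) + "\n")
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    sys.exit(main())
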