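"""Shared fixtures: hand-constructed traces with exactly known geometry."""

from __future__ import annotations

import numpy as np
import pytest

from eyeblink.preprocess import NormalizedTrial
from eyeblink.protocol import Phase, ProtocolConfig, TrialKind, TrialPlan
from eyeblink.simulate import TrialTrace

RATE = 1000.0  # Hz
T0 = 1000.0  # CS onset within the constructed traces, ms
DUR = 2500.0  # ms


def plan_of(kind: TrialKind, phase: Phase = Phase.ACQUISITION) -> TrialPlan:
    if kind is TrialKind.US_ONLY:
        phase = Phase.EXTINCTION
    return TrialPlan(0, phase, 0, 0, kind)


def build_normalized(
    fn, kind: TrialKind = TrialKind.CS_ONLY, t0: float = T0, dur: float = DUR
) -> NormalizedTrial:
    """Normalized trial whose samples are ``fn(t_ms_rel_cs)`` (vectorized)."""
    t = np.arange(int(dur)) * 1000.0 / RATE
    samples = np.asarray(fn(t - t0), dtype=float)
    has_us = kind in (TrialKind.PAIRED, TrialKind.US_ONLY)
    markers = {
        "cs_onset": t0 if kind is not TrialKind.US_ONLY else None,
        "cs_offset": t0 + 280.0 if kind is not TrialKind.US_ONLY else None,
        "us_onset": t0 + 250.0 if has_us else None,
        "us_offset": t0 + 280.0 if has_us else None,
    }
    ref = t0 if kind is not TrialKind.US_ONLY else t0 + 250.0
    return NormalizedTrial(
        plan_of(kind), samples, RATE, ref, markers, baseline_value=0.0, ur_peak_raw=None
    )


def build_raw_trace(
    fn, kind: TrialKind = TrialKind.PAIRED, t0: float = T0, dur: float = DUR
) -> TrialTrace:
    """Raw trace whose samples are ``fn(t_ms_rel_cs)`` in sensor units."""
    t = np.arange(int(dur)) * 1000.0 / RATE
    samples = np.asarray(fn(t - t0), dtype=float)
    has_us = kind in (TrialKind.PAIRED, TrialKind.US_ONLY)
    markers = {
        "cs_onset": t0 if kind is not TrialKind.US_ONLY else None,
        "cs_offset": t0 + 280.0 if kind is not TrialKind.US_ONLY else None,
        "us_onset": t0 + 250.0 if has_us else None,
        "us_offset": t0 + 280.0 if has_us else None,
    }
    ref = t0 if kind is not TrialKind.US_ONLY else t0 + 250.0
    return TrialTrace(plan_of(kind), samples, RATE, ref, markers)


@pytest.fixture
def protocol() -> ProtocolConfig:
    return ProtocolConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
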