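"""Trace normalization and trial-quality rules.

Raw eyelid traces are expressed in sensor volts; analysis operates on
UR-normalized units in which the pre-CS baseline maps to 0 and the peak of
the unconditioned reflex blink maps to 1.  Paired trials normalize against
their own UR; CS-only probe trials borrow the UR range of the most recent
paired trial in the session.  Additional rules implemented here:

* baseline-stability / adaptive-ITI criterion: the trial may only start once
  every sample of the final 1 s pre-CS window stays within ±10% of the
  average UR amplitude around the window median, extending the intertrial
  interval 1 s at a time otherwise;
* zero-phase moving-average smoothing (timing metrics are computed on
  smoothed traces);
* early-movement exclusion: trials whose normalized response exceeds 0.05
  between 0 and 99 ms after CS onset are excluded from CR scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .protocol import ConfigurationError, TrialKind
from .simulate import TrialTrace


class ExclusionReason(str, Enum):
    NONE = "none"
    EARLY_MOVEMENT = "early_movement"
    UNSTABLE_BASELINE = "unstable_baseline"
    NO_UR_REFERENCE = "no_ur_reference"
    DEGENERATE_REFERENCE = "degenerate_reference"


@dataclass(frozen=True)
class BaselineCriterion:
    """Adaptive-ITI stability rule: the 1 s pre-CS window must stay within
    ±``allowed_range`` of the average UR amplitude; each failure adds
    ``iti_extension_s`` to the intertrial interval."""

    window_s: float = 1.0
    allowed_range: float = 0.10  # fraction of average UR amplitude
    iti_extension_s: float = 1.0

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.allowed_range <= 0:
            raise ConfigurationError("window and allowed_range must be positive")


@dataclass
class NormalizedTrial:
    """A trial in UR-normalized units plus bookkeeping for exclusions."""

    plan: object
    samples: np.ndarray
    sampling_rate_hz: float
    t0_ms: float  # analysis reference (CS onset, or US onset on US-only trials)
    markers: dict
    baseline_value: float
    ur_peak_raw: float | None
    valid: bool = True
    exclusion_reason: ExclusionReason = ExclusionReason.NONE
    ground_truth: dict = field(default_factory=dict)

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to the analysis reference t0."""
        return np.arange(self.samples.size) * 1000.0 / self.sampling_rate_hz - self.t0_ms

    def window(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Samples in the closed window [start_ms, end_ms] relative to t0."""
        t = self.times_ms
        return self.samples[(t >= start_ms) & (t <= end_ms)]


class ReferenceError(ValueError):
    """Raised when a UR reference needed for normalization is unusable."""


def check_baseline_stability(
    segment: np.ndarray,
    criterion: BaselineCriterion,
    ur_average: float,
    sampling_rate_hz: float = 1000.0,
) -> tuple[bool, int]:
    """Evaluate the pre-CS stability rule on a raw pre-trial segment.

    Returns ``(stable, extensions_needed)``: ``stable`` is True iff every
    sample of the final window lies within ±allowed_range*ur_average of the
    window median; ``extensions_needed`` counts how many 1 s forward shifts
    from the earliest possible CS time were required before a stable window
    appeared (the quantity the simulation loop adds to the ITI).
    """
    if ur_average <= 0:
        raise ReferenceError("ur_average must be positive")
    w = int(round(criterion.window_s * sampling_rate_hz))
    if segment.size < w:
        raise ConfigurationError("segment shorter than the stability window")
    tol = criterion.allowed_range * ur_average

    def _ok(win: np.ndarray) -> bool:
        return bool(np.all(np.abs(win - np.median(win)) <= tol))

    stable = _ok(segment[-w:])
    step = int(round(criterion.iti_extension_s * sampling_rate_hz))
    extensions = 0
    pos = w
    while pos <= segment.size:
        if _ok(segment[pos - w : pos]):
            break
        extensions += 1
        pos += step
    else:
        extensions = (segment.size - w) // step + 1
    return stable, extensions


def normalize_trial(
    trace: TrialTrace,
    last_paired_ur_range: float | None = None,
    baseline_window_ms: float = 500.0,
    ur_search_ms: float = 200.0,
) -> NormalizedTrial:
    """Normalize one trial to baseline -> 0, UR peak -> 1.

    ``baseline`` is the mean over the ``baseline_window_ms`` immediately
    before the analysis reference (CS onset, or US onset on US-only trials);
    on US trials the UR peak is the raw maximum within
    [US onset, US onset + ur_search_ms].  CS-only trials are scaled by
    ``last_paired_ur_range`` (raw peak minus baseline of the most recent
    paired trial); without such a reference the trial is marked invalid.
    """
    t = np.arange(trace.samples.size) * 1000.0 / trace.sampling_rate_hz
    pre = trace.samples[(t >= trace.t0_ms - baseline_window_ms) & (t < trace.t0_ms)]
    if pre.size == 0:
        raise ConfigurationError("trace has no pre-stimulus baseline window")
    baseline = float(np.mean(pre))

    has_us = trace.markers.get("us_onset") is not None
    ur_peak_raw: float | None = None
    if has_us:
        us_on = trace.markers["us_onset"]
        ur_seg = trace.samples[(t >= us_on) & (t <= us_on + ur_search_ms)]
        ur_peak_raw = float(np.max(ur_seg))
        ur_range = ur_peak_raw - baseline
    else:
        if last_paired_ur_range is None:
            return NormalizedTrial(
                trace.plan, trace.samples.copy(), trace.sampling_rate_hz,
                trace.t0_ms, trace.markers, baseline, None,
                valid=False, exclusion_reason=ExclusionReason.NO_UR_REFERENCE,
                ground_truth=trace.ground_truth,
            )
        ur_range = last_paired_ur_range
    if ur_range <= 0:
        return NormalizedTrial(
            trace.plan, trace.samples.copy(), trace.sampling_rate_hz,
            trace.t0_ms, trace.markers, baseline, ur_peak_raw,
            valid=False, exclusion_reason=ExclusionReason.DEGENERATE_REFERENCE,
            ground_truth=trace.ground_truth,
        )
    samples = (trace.samples - baseline) / ur_range
    return NormalizedTrial(
        trace.plan, samples, trace.sampling_rate_hz, trace.t0_ms, trace.markers,
        baseline, ur_peak_raw, ground_truth=trace.ground_truth,
    )


def normalize_session(
    traces: list[TrialTrace],
    mode: str = "per_trial",
    baseline_window_ms: float = 500.0,
    ur_search_ms: float = 200.0,
) -> list[NormalizedTrial]:
    """Normalize a session of trials.

    ``mode="per_trial"`` (default): each US trial is scaled by its own UR,
    and CS-only probes carry forward the UR range of the most recent
    preceding paired trial.  ``mode="session_average"``: every trial is
    scaled by the session-wide mean UR range — the alternative scheme that
    should give indistinguishable session metrics.
    """
    kwargs = dict(baseline_window_ms=baseline_window_ms, ur_search_ms=ur_search_ms)
    if mode == "session_average":
        ranges = []
        for tr in traces:
            nt = normalize_trial(tr, **kwargs)
            if nt.valid and nt.ur_peak_raw is not None:
                ranges.append(nt.ur_peak_raw - nt.baseline_value)
        if not ranges:
            raise ReferenceError("session has no usable UR trials to average")
        avg = float(np.mean(ranges))
        out = []
        for tr in traces:
            t = np.arange(tr.samples.size) * 1000.0 / tr.sampling_rate_hz
            pre = tr.samples[(t >= tr.t0_ms - baseline_window_ms) & (t < tr.t0_ms)]
            baseline = float(np.mean(pre))
            out.append(
                NormalizedTrial(
                    tr.plan, (tr.samples - baseline) / avg, tr.sampling_rate_hz,
                    tr.t0_ms, tr.markers, baseline, None,
                    ground_truth=tr.ground_truth,
                )
            )
        return out
    if mode != "per_trial":
        raise ConfigurationError(f"unknown normalization mode {mode!r}")
    out = []
    carried: float | None = None
    for tr in traces:
        if tr.plan.kind is TrialKind.CS_ONLY:
            nt = normalize_trial(tr, last_paired_ur_range=carried, **kwargs)
        else:
            nt = normalize_trial(tr, **kwargs)
            if nt.valid and nt.ur_peak_raw is not None:
                carried = nt.ur_peak_raw - nt.baseline_value
        out.append(nt)
    return out


def smooth(samples: np.ndarray, width_ms: float = 10.0, sampling_rate_hz: float = 1000.0) -> np.ndarray:
    """Zero-phase moving average; edges use edge-value padding so a constant
    trace maps to itself and the output length equals the input length."""
    k = max(int(round(width_ms * sampling_rate_hz / 1000.0)), 1)
    if k > samples.size:
        raise ConfigurationError("smoothing kernel wider than the trace")
    if k == 1:
        return samples.astype(float).copy()
    pad_l, pad_r = k // 2, k - 1 - k // 2
    padded = np.concatenate(
        [np.full(pad_l, samples[0]), samples, np.full(pad_r, samples[-1])]
    )
    kernel = np.full(k, 1.0 / k)
    return np.convolve(padded, kernel, mode="valid")


def smoothed(trial: NormalizedTrial, width_ms: float = 10.0) -> NormalizedTrial:
    """Return a copy of the trial with smoothed samples."""
    return NormalizedTrial(
        trial.plan, smooth(trial.samples, width_ms, trial.sampling_rate_hz),
        trial.sampling_rate_hz, trial.t0_ms, trial.markers,
        trial.baseline_value, trial.ur_peak_raw, trial.valid,
        trial.exclusion_reason, trial.ground_truth,
    )


def early_movement_flag(
    trial: NormalizedTrial, threshold: float = 0.05, window_ms: tuple[float, float] = (0.0, 99.0)
) -> bool:
    """True iff the normalized response exceeds ``threshold`` in the closed
    early window after CS onset (strict inequality at the boundary)."""
    if not trial.valid:
        raise ConfigurationError("early-movement rule requires a valid normalized trial")
    seg = trial.window(*window_ms)
    return bool(seg.size) and float(np.max(seg)) > threshold
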