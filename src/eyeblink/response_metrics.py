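"""Detection and timing of conditioned and unconditioned responses.

CR scoring operates on unpaired CS probe trials: a trial scores as a CR if
the normalized response exceeds 0.15 between 100 and 400 ms after CS onset
while staying below 0.05 in the first 99 ms (early movements are excluded).
Timing of a scored CR is described by three parameters:

* onset latency — time from CS onset to a change in concavity of the
  eyelid trace, operationalized as the last sign change (<= 0 to > 0) of the
  smoothed second derivative before the 10%-of-peak crossing;
* 10-90% rise time — time between the 10% and 90% crossings of the peak
  amplitude;
* peak latency — time from CS onset to the maximum of the smoothed trace.

UR metrics (latency, rise time, peak velocity) use the same detectors,
referenced to US onset and searched within 75 ms of it.  Photic eyelid
openings — non-associative, negative-going deflections to the light CS —
are counted when the trace dips more than 5% below baseline 70-250 ms after
CS onset but not before, and only in sessions before CRs have appeared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .preprocess import NormalizedTrial, early_movement_flag, smooth
from .protocol import ConfigurationError, TrialKind

CR_WINDOW = (100.0, 400.0)
CR_THRESHOLD = 0.15
PRE_THRESHOLD = 0.05


class UndetectedURError(ValueError):
    """No unconditioned reflex found where one was required."""


@dataclass
class CRMetrics:
    is_cr: bool
    excluded: bool
    onset_latency_ms: float | None = None
    rise_time_10_90_ms: float | None = None
    peak_latency_ms: float | None = None
    peak_amplitude: float | None = None
    onset_fallback: bool = False  # concavity detector fell back to 5% crossing


@dataclass
class URMetrics:
    latency_ms: float
    rise_time_ms: float
    peak_amplitude: float
    peak_velocity: float  # normalized units / ms


@dataclass
class OpeningEvent:
    detected: bool
    depth: float | None = None  # negative, normalized units
    time_ms: float | None = None


def classify_cr(
    trial: NormalizedTrial,
    cr_threshold: float = CR_THRESHOLD,
    pre_threshold: float = PRE_THRESHOLD,
    window_ms: tuple[float, float] = CR_WINDOW,
    smooth_width_ms: float = 10.0,
) -> str:
    """Score a CS-only probe trial as ``"cr"``, ``"none"`` or ``"excluded"``.

    Thresholds are applied to the smoothed trace (as all scoring rules are);
    raw 1 kHz sensor noise would otherwise trip the early-movement rule on
    most trials.
    """
    if trial.plan.kind is not TrialKind.CS_ONLY:
        raise ConfigurationError("CR scoring applies to CS-only probe trials")
    if not trial.valid:
        return "excluded"
    from .preprocess import smoothed as _smoothed

    sm = _smoothed(trial, smooth_width_ms) if smooth_width_ms > 0 else trial
    if early_movement_flag(sm, threshold=pre_threshold):
        return "excluded"
    seg = sm.window(*window_ms)
    return "cr" if seg.size and float(np.max(seg)) > cr_threshold else "none"


def _crossing_time(t: np.ndarray, x: np.ndarray, level: float, start_idx: int) -> float | None:
    """First time at/after start_idx where x crosses up through ``level``,
    linearly interpolated between samples."""
    start_idx = max(start_idx, 0)
    if start_idx >= x.size:
        return None
    if x[start_idx] >= level:
        return float(t[start_idx])
    xs = x[start_idx:]
    up = np.flatnonzero((xs[1:] >= level) & (xs[:-1] < level))
    if up.size == 0:
        return None
    i = start_idx + int(up[0]) + 1
    frac = (level - x[i - 1]) / (x[i] - x[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


_SAVGOL_MS = 25.0  # second-derivative estimation window


def _concavity_onset(
    t: np.ndarray, x: np.ndarray, cross_time: float, search_start_idx: int,
    sampling_rate_hz: float, smooth_width_ms: float = 10.0,
) -> float | None:
    """Change-of-concavity onset: latest time before the 10%-of-peak
    crossing at which the second derivative of the smoothed trace turns from
    <= 0 to > 0.

    Zero-phase smoothing (moving average plus the Savitzky-Golay derivative
    window) advances the leading edge of the curvature transient by half the
    combined kernel width, so that known half-width is added back; the
    estimate is capped at the crossing time itself.
    """
    win = max(int(round(_SAVGOL_MS * sampling_rate_hz / 1000.0)) | 1, 5)
    if x.size <= win:
        return None
    d2 = savgol_filter(x, window_length=win, polyorder=2, deriv=2)
    cross_idx = min(int(np.searchsorted(t, cross_time)), d2.size - 1)
    lo = max(search_start_idx, 1)
    # The movement's curvature transient is at least as wide as the kernels.
    # Brief negative dips inside it are smoothed-noise sign flips: close gaps
    # shorter than ~a third of the derivative window before finding the run.
    pos = d2 > 0
    gap = max(int(round(win / 3)), 1)
    if gap > 1:
        from scipy.ndimage import binary_closing

        pos = binary_closing(pos, structure=np.ones(gap, dtype=bool))
    min_run = int(round(0.6 * win))
    comp = 0.5 * (smooth_width_ms + _SAVGOL_MS)
    i = cross_idx
    while i > lo:
        if not pos[i]:
            i -= 1
            continue
        start = i
        while start > lo and pos[start - 1]:
            start -= 1
        if i - start + 1 >= min_run or (pos[cross_idx] and start <= cross_idx <= i):
            return float(min(t[start] + comp, cross_time))
        i = start - 1
    return None


def cr_timing(
    trial: NormalizedTrial,
    window_ms: tuple[float, float] = CR_WINDOW,
    smooth_width_ms: float = 10.0,
    search_start_ms: float = 20.0,
) -> CRMetrics:
    """Timing metrics for a CS-only trial already scored as a CR."""
    status = classify_cr(trial, window_ms=window_ms)
    if status == "excluded":
        return CRMetrics(is_cr=False, excluded=True)
    if status != "cr":
        return CRMetrics(is_cr=False, excluded=False)

    x = smooth(trial.samples, smooth_width_ms, trial.sampling_rate_hz)
    t = trial.times_ms
    in_win = (t >= window_ms[0]) & (t <= window_ms[1])
    idx_win = np.flatnonzero(in_win)
    peak_rel = int(np.argmax(x[idx_win]))  # ties -> earliest, argmax contract
    peak_idx = int(idx_win[peak_rel])
    peak_amp = float(x[peak_idx])
    peak_latency = float(t[peak_idx])

    start_idx = int(np.searchsorted(t, search_start_ms))
    t10 = _crossing_time(t, x, 0.1 * peak_amp, start_idx)
    cross_time = t10 if t10 is not None else float(t[peak_idx])
    onset = _concavity_onset(
        t, x, cross_time, start_idx, trial.sampling_rate_hz, smooth_width_ms
    )
    fallback = False
    if onset is None:
        onset = _crossing_time(t, x, 0.05 * peak_amp, start_idx)
        fallback = True
    if onset is None:
        onset = float(t[start_idx])
        fallback = True

    onset_idx = int(np.searchsorted(t, onset))
    t10b = _crossing_time(t, x, 0.1 * peak_amp, onset_idx)
    t90 = _crossing_time(t, x, 0.9 * peak_amp, onset_idx)
    rise = (t90 - t10b) if (t10b is not None and t90 is not None) else None
    return CRMetrics(
        is_cr=True, excluded=False,
        onset_latency_ms=float(onset),
        rise_time_10_90_ms=rise,
        peak_latency_ms=peak_latency,
        peak_amplitude=peak_amp,
        onset_fallback=fallback,
    )


def ur_metrics(
    trial: NormalizedTrial,
    latency_window_ms: float = 75.0,
    peak_search_ms: float = 200.0,
    smooth_width_ms: float = 10.0,
) -> URMetrics:
    """Latency, 10-90% rise time, peak amplitude and peak velocity of the
    unconditioned reflex blink, referenced to US onset."""
    us_on = trial.markers.get("us_onset")
    if us_on is None:
        raise ConfigurationError("UR metrics require a trial with a US")
    x = smooth(trial.samples, smooth_width_ms, trial.sampling_rate_hz)
    t_trace = np.arange(x.size) * 1000.0 / trial.sampling_rate_hz
    t = t_trace - us_on  # ms relative to US onset

    epoch = (t >= 0) & (t <= peak_search_ms)
    idx = np.flatnonzero(epoch)
    peak_rel = int(np.argmax(x[idx]))
    peak_idx = int(idx[peak_rel])
    peak_amp = float(x[peak_idx])
    if peak_amp <= 0:
        raise UndetectedURError("no positive deflection after the US")

    start_idx = int(idx[0])
    t10 = _crossing_time(t, x, 0.1 * peak_amp, start_idx)
    if t10 is None:
        raise UndetectedURError("no deflection above 10% of the UR scale")
    onset = _concavity_onset(
        t, x, t10, start_idx, trial.sampling_rate_hz, smooth_width_ms
    )
    if onset is None:
        onset = t10
    if onset > latency_window_ms:
        raise UndetectedURError("no UR onset within the latency window")

    t90 = _crossing_time(t, x, 0.9 * peak_amp, start_idx)
    if t10 is None or t90 is None:
        raise UndetectedURError("UR rise not resolvable")
    dt = 1000.0 / trial.sampling_rate_hz
    vel = float(np.max(np.diff(x[idx])) / dt)
    return URMetrics(float(onset), float(t90 - t10), peak_amp, vel)


def detect_photic_opening(
    trial: NormalizedTrial,
    session_has_crs: bool,
    depth_threshold: float = -0.05,
    window_ms: tuple[float, float] = (70.0, 250.0),
) -> OpeningEvent:
    """Count a photic eyelid opening: a dip below ``depth_threshold`` within
    70-250 ms of CS onset, with no such dip earlier in the trial, and only
    while the session has produced no CRs yet."""
    if session_has_crs:
        return OpeningEvent(False)
    seg = trial.window(*window_ms)
    pre = trial.window(0.0, window_ms[0] - 1e-9)
    if seg.size == 0:
        return OpeningEvent(False)
    min_val = float(np.min(seg))
    early_ok = pre.size == 0 or float(np.min(pre)) >= depth_threshold
    if min_val < depth_threshold and early_ok:
        t = trial.times_ms
        mask = (t >= window_ms[0]) & (t <= window_ms[1])
        tmin = float(t[mask][int(np.argmin(trial.samples[mask]))])
        return OpeningEvent(True, depth=min_val, time_ms=tmin)
    return OpeningEvent(False)
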