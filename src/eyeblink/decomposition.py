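"""Separation of response probability from response amplitude.

The per-session learning measure is built from the distribution of per-trial
peak eyelid amplitudes in a CS measurement window.  Trials with no response
scatter symmetrically about zero (sensor noise moves the eyelid up or down
with equal probability), so the negative half of the amplitude histogram,
reflected across zero together with the zero-centered bin, estimates the
"failure" (non-response) distribution.  Its integral is the failure rate:

    probability = 1 - failure_rate

and the response amplitude is the center of mass of the histogram that
remains after subtracting the reflected failure distribution.  This
decomposes learning into how often a response occurs (probability) and how
big it is when it occurs (amplitude) — quantities a fixed %CR threshold
conflates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import NormalizedTrial, smooth
from .protocol import TrialKind

#: Default measurement windows (ms from CS onset).  Paired trials stop at the
#: US onset (250 ms) so the reflex blink cannot contaminate the peak; CS-only
#: probes, with no US delivered, extend to the CS offset (280 ms).
PAIRED_WINDOW = (100.0, 250.0)
CS_ONLY_WINDOW = (100.0, 280.0)
DEFAULT_BIN_WIDTH = 0.025


class EmptySessionError(ValueError):
    pass


@dataclass
class AmplitudeSampleSet:
    """Per-trial signed peak amplitudes for one session."""

    values: np.ndarray
    window_ms: tuple[float, float]
    n_trials: int


@dataclass
class ResponseHistogram:
    """Amplitude histogram with one bin centered exactly on zero."""

    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def zero_bin(self) -> int:
        """Index of the bin spanning [-w/2, +w/2]."""
        return int(np.argmin(np.abs(self.centers)))


@dataclass
class DecompositionResult:
    failure_rate: float
    probability: float
    amplitude: float | None  # undefined (None) when no response mass remains
    response_mass: np.ndarray
    nonresponse_mass: np.ndarray
    bin_centers: np.ndarray


def signed_extremum(values: np.ndarray) -> float:
    """The value of greatest displacement from 0, carrying its sign, so that
    eyelid openings populate negative histogram bins."""
    if values.size == 0:
        raise EmptySessionError("empty measurement window")
    return float(values[int(np.argmax(np.abs(values)))])


def collect_peak_amplitudes(
    session: list[NormalizedTrial],
    window_ms: tuple[float, float] | None = None,
    smooth_width_ms: float = 10.0,
) -> AmplitudeSampleSet:
    """Signed window-peak amplitude for every valid CS trial of a session.

    US-only trials carry no CS window and are excluded.  Peaks are read from
    smoothed traces.  ``window_ms=None`` applies the kind-specific defaults
    (100-250 ms paired, 100-280 ms CS-only).
    """
    values = []
    used_window = window_ms
    for tr in session:
        if not tr.valid or tr.plan.kind is TrialKind.US_ONLY:
            continue
        win = window_ms
        if win is None:
            win = PAIRED_WINDOW if tr.plan.kind is TrialKind.PAIRED else CS_ONLY_WINDOW
            used_window = (100.0, 280.0)
        x = smooth(tr.samples, smooth_width_ms, tr.sampling_rate_hz)
        t = tr.times_ms
        seg = x[(t >= win[0]) & (t <= win[1])]
        values.append(signed_extremum(seg))
    if not values:
        raise EmptySessionError("session has no valid CS trials")
    return AmplitudeSampleSet(np.asarray(values, dtype=float), used_window, len(values))


def build_histogram(
    samples: AmplitudeSampleSet | np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH
) -> ResponseHistogram:
    """Histogram the amplitudes with bins tiled so that one bin spans exactly
    [-bin_width/2, +bin_width/2]."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    v = samples.values if isinstance(samples, AmplitudeSampleSet) else np.asarray(samples, float)
    half = bin_width / 2.0
    n_neg = max(int(np.ceil((-(v.min()) - half) / bin_width)), 0) if v.size else 0
    n_pos = max(int(np.ceil((v.max() - half) / bin_width)), 0) if v.size else 0
    edges = np.arange(-n_neg - 0.5, n_pos + 0.5 + 1e-9) * bin_width
    counts, _ = np.histogram(v, bins=edges)  # last bin closed on both ends
    return ResponseHistogram(edges, counts.astype(int))


def reflect_and_decompose(
    hist: ResponseHistogram, noise_mask_z: float = 2.0
) -> DecompositionResult:
    """Reflect the negative-amplitude histogram across zero to estimate the
    failure distribution; derive probability and amplitude.

    The zero-centered bin is assigned wholly to the non-response mass (it is
    the "failure to respond" peak).  After subtracting the reflected negative
    counts from the positive side, per-bin mass is floored at 0, probability
    is ``1 - failure_rate`` (both clamped to [0, 1]), and amplitude is the
    center of mass of the remaining response distribution — ``None`` when no
    response mass remains.

    Flooring leaves a positive-biased residual in bins inside the failure
    support (``max(pos - reflected, 0)`` has positive expectation when the
    two counts have equal rates), which drags the center of mass toward zero
    when responses are rare.  The amplitude therefore ignores bins whose
    floored mass does not exceed ``noise_mask_z`` times the counting noise
    of the subtraction, ``sqrt(2 * reflected)``; bins with no reflected mass
    are never masked.  Set ``noise_mask_z=0`` for the plain floored center
    of mass.
    """
    total = hist.total
    if total == 0:
        raise EmptySessionError("empty histogram")
    counts = hist.counts.astype(float)
    centers = hist.centers
    z = hist.zero_bin

    nonresponse = np.zeros_like(counts)
    nonresponse[z] = counts[z]
    nonresponse[:z] = counts[:z]  # negative side stays as observed
    response = np.zeros_like(counts)
    response[z + 1 :] = counts[z + 1 :]
    reflected = np.zeros_like(counts)
    # mirror each negative bin onto its positive counterpart
    for j in range(z):
        mirror = 2 * z - j
        refl = counts[j]
        if refl == 0:
            continue
        if mirror < counts.size:
            nonresponse[mirror] += refl
            reflected[mirror] += refl
            response[mirror] = max(response[mirror] - refl, 0.0)
        else:
            # mirrored mass falls beyond the observed positive range: it
            # still counts toward the failure integral
            nonresponse = np.append(nonresponse, refl)
            response = np.append(response, 0.0)
            reflected = np.append(reflected, refl)
            centers = np.append(centers, -centers[j])

    failure_rate = float(np.clip(nonresponse.sum() / total, 0.0, 1.0))
    probability = float(np.clip(1.0 - failure_rate, 0.0, 1.0))
    keep = response > noise_mask_z * np.sqrt(2.0 * reflected)
    masked = np.where(keep, response, 0.0)
    resp_total = masked.sum()
    amplitude = float(np.sum(centers * masked) / resp_total) if resp_total > 0 else None
    return DecompositionResult(
        failure_rate, probability, amplitude, response, nonresponse, centers
    )


def decompose_amplitudes(
    values: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH
) -> DecompositionResult:
    """Convenience: histogram + reflection in one call."""
    return reflect_and_decompose(build_histogram(np.asarray(values, float), bin_width))


def percent_cr(values: np.ndarray, cr_threshold: float = 0.15) -> float:
    """Classical %CR measure: percentage of trials whose window peak exceeds
    the fixed threshold."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise EmptySessionError("no trials")
    return 100.0 * float(np.mean(v > cr_threshold))


def session_metrics(
    session: list[NormalizedTrial],
    window_ms: tuple[float, float] | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    cr_threshold: float = 0.15,
) -> dict[str, float | None]:
    """Per-session summary: decomposition probability and amplitude plus the
    threshold-based %CR, with the number of contributing trials."""
    samples = collect_peak_amplitudes(session, window_ms)
    res = reflect_and_decompose(build_histogram(samples, bin_width))
    return {
        "n_trials": samples.n_trials,
        "probability": res.probability,
        "amplitude": res.amplitude,
        "percent_cr": percent_cr(samples.values, cr_threshold),
    }
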