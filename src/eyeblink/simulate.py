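"""Generative eyelid-trace simulator with ground-truth labels.

The simulator emulates the head-fixed delay-conditioning experiment: on each
CS trial a conditioned response (CR) occurs with a session-dependent
probability ``p_s`` and, when it occurs, takes the form of a bell-shaped
eyelid closure that peaks at the expected US time.  US delivery evokes a
reflex blink (UR) whose raw amplitude defines the normalization scale.
Traces additionally carry Gaussian sensor noise, slow baseline drift, and
occasional negative-going photic eyelid openings to the light CS.

Learning dynamics are saturating exponentials in the session index:

    p_s = p_max * (1 - exp(-s / tau_sessions))

with an analogous curve for CR amplitude, a decaying curve during
extinction, and a head-start ("savings") offset during reacquisition.  Every
trial records its ground truth (response present, true amplitude, true onset
and rise time), so downstream estimators can be validated by parameter
recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import truncnorm

from .protocol import (
    ConfigurationError,
    Phase,
    ProtocolConfig,
    TrialKind,
    TrialPlan,
    build_acquisition_schedule,
    build_extinction_schedule,
)

# Fraction of the onset->peak interval that the 10-90% rise may occupy; onset
# draws are truncated so the bell geometry stays feasible.
_MAX_RISE_FRACTION = 0.92


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one subject's eyelid traces.

    Amplitudes are in UR-normalized units (baseline 0, UR peak 1) unless the
    name says volts; times in ms.  ``noise_sigma`` is the per-sample sensor
    noise; drift is a slow sinusoid of the given amplitude and period.
    """

    sampling_rate_hz: float = 1000.0
    trace_duration_ms: float = 2500.0
    cs_onset_in_trace_ms: float = 1000.0  # leaves a >= 1 s baseline window
    noise_sigma: float = 0.02
    drift_amplitude: float = 0.03
    drift_timescale_s: float = 20.0
    # learning dynamics (session index is 1-based)
    p_max: float = 0.55
    tau_sessions: float = 4.0
    amp_max: float = 0.45
    amp_tau_sessions: float = 4.0
    amp_sd: float = 0.05
    extinction_tau_sessions: float = 1.2
    reacq_savings_sessions: float = 4.0
    # CR timing
    cr_onset_mean_ms: float = 145.0
    cr_onset_sd_ms: float = 10.0
    cr_rise_ms: float = 90.0
    # UR shape
    ur_latency_mean_ms: float = 30.0
    ur_latency_sd_ms: float = 5.0
    ur_rise_ms: float = 80.0
    ur_decay_ms: float = 150.0
    ur_peak_volts: float = 1.0
    baseline_volts: float = 2.0
    # photic eyelid opening
    opening_prob: float = 0.05
    opening_depth: float = 0.12
    # between-subject heterogeneity applied by the cohort builder
    subject_pmax_sd: float = 0.05
    subject_amp_sd: float = 0.03
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_max <= 1.0):
            raise ConfigurationError("p_max must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.sampling_rate_hz <= 0 or self.tau_sessions <= 0:
            raise ConfigurationError("sampling_rate and tau_sessions must be positive")
        for name in (
            "trace_duration_ms",
            "cs_onset_in_trace_ms",
            "cr_rise_ms",
            "ur_rise_ms",
            "ur_decay_ms",
            "ur_peak_volts",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ConfigurationError(f"{name} must be positive and finite")


@dataclass
class TrialTrace:
    """One simulated (or recorded) trial: raw samples plus stimulus markers.

    ``markers`` holds cs_onset/cs_offset/us_onset/us_offset in ms from trace
    start (None where the stimulus was not delivered); ``t0`` is the analysis
    reference: CS onset for CS trials, US onset for US-only trials.
    ``ground_truth`` is present only for simulated data.
    """

    plan: TrialPlan
    samples: np.ndarray
    sampling_rate_hz: float
    t0_ms: float
    markers: dict[str, float | None]
    ground_truth: dict[str, object] = field(default_factory=dict)

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * 1000.0 / self.sampling_rate_hz


def session_true_state(
    cfg: SimulationConfig, phase: Phase, session_number: int, protocol: ProtocolConfig
) -> tuple[float, float]:
    """Ground-truth (response probability, mean CR amplitude) for a session.

    ``session_number`` is 1-based within the phase.
    """
    s = session_number
    if s < 1:
        raise ConfigurationError("session_number is 1-based")
    learn = lambda n, tau, top: top * (1.0 - np.exp(-n / tau))
    if phase in (Phase.ACQUISITION, Phase.HABITUATION):
        if phase is Phase.HABITUATION:
            return 0.0, 0.0
        return (
            learn(s, cfg.tau_sessions, cfg.p_max),
            learn(s, cfg.amp_tau_sessions, cfg.amp_max),
        )
    n_acq = protocol.n_acquisition_sessions
    p_end = learn(n_acq, cfg.tau_sessions, cfg.p_max)
    a_end = learn(n_acq, cfg.amp_tau_sessions, cfg.amp_max)
    if phase is Phase.EXTINCTION:
        return p_end * float(np.exp(-s / cfg.extinction_tau_sessions)), a_end
    if phase is Phase.REACQUISITION:
        # savings: reacquisition behaves like acquisition with a head start
        return (
            learn(s + cfg.reacq_savings_sessions, cfg.tau_sessions, cfg.p_max),
            learn(s + cfg.reacq_savings_sessions, cfg.amp_tau_sessions, cfg.amp_max),
        )
    raise ConfigurationError(f"unknown phase {phase}")


def cr_bell(
    t_ms: np.ndarray,
    onset_ms: float,
    peak_ms: float,
    rise_10_90_ms: float,
    amplitude: float,
) -> np.ndarray:
    """Bell-shaped CR waveform with controllable onset, peak time and rise.

    A monotone PCHIP segment passes through (onset, 0), (t10, 0.1A),
    (t90, 0.9A), (peak, A) so the 10-90% rise time equals
    ``rise_10_90_ms`` exactly; the decay mirrors the rise about the peak.
    """
    slack = peak_ms - onset_ms - rise_10_90_ms
    if slack <= 0:
        raise ConfigurationError("rise time must be shorter than onset->peak interval")
    t10 = onset_ms + 0.3 * slack
    t90 = t10 + rise_10_90_ms
    knots_t = np.array([onset_ms, t10, t90, peak_ms])
    knots_y = np.array([0.0, 0.1, 0.9, 1.0]) * amplitude
    rise_fn = PchipInterpolator(knots_t, knots_y)
    out = np.zeros_like(t_ms, dtype=float)
    rising = (t_ms >= onset_ms) & (t_ms <= peak_ms)
    out[rising] = rise_fn(t_ms[rising])
    falling = (t_ms > peak_ms) & (t_ms < 2 * peak_ms - onset_ms)
    out[falling] = rise_fn(2 * peak_ms - t_ms[falling])
    return out


def ur_pulse(
    t_rel_us_ms: np.ndarray, latency_ms: float, rise_ms: float, decay_ms: float
) -> np.ndarray:
    """Reflex-blink waveform: delayed linear rise to 1 then exponential decay."""
    out = np.zeros_like(t_rel_us_ms, dtype=float)
    t = t_rel_us_ms - latency_ms
    rising = (t >= 0) & (t < rise_ms)
    out[rising] = t[rising] / rise_ms
    after = t >= rise_ms
    out[after] = np.exp(-(t[after] - rise_ms) / decay_ms)
    return out


def _opening_dip(
    t_rel_cs_ms: np.ndarray, center_ms: float, depth: float, width_ms: float = 140.0
) -> np.ndarray:
    """Negative-going photic eyelid opening: a raised-cosine dip."""
    out = np.zeros_like(t_rel_cs_ms, dtype=float)
    lo, hi = center_ms - width_ms / 2, center_ms + width_ms / 2
    inside = (t_rel_cs_ms >= lo) & (t_rel_cs_ms <= hi)
    out[inside] = -depth * 0.5 * (
        1.0 - np.cos(2 * np.pi * (t_rel_cs_ms[inside] - lo) / width_ms)
    )
    return out


def _draw_cr_params(
    cfg: SimulationConfig, amp_mean: float, rng: np.random.Generator
) -> tuple[float, float, float]:
    """Sample (onset, amplitude, rise) for one CR, keeping geometry feasible."""
    peak = 250.0  # CR peaks at the (expected) US onset, ms from CS onset
    onset_hi = peak - cfg.cr_rise_ms / _MAX_RISE_FRACTION
    onset_lo = 60.0
    if onset_hi <= onset_lo:
        raise ConfigurationError("cr_rise_ms too long for the CS-US interval")
    a, b = (
        (onset_lo - cfg.cr_onset_mean_ms) / max(cfg.cr_onset_sd_ms, 1e-9),
        (onset_hi - cfg.cr_onset_mean_ms) / max(cfg.cr_onset_sd_ms, 1e-9),
    )
    onset = float(
        truncnorm.rvs(a, b, loc=cfg.cr_onset_mean_ms, scale=max(cfg.cr_onset_sd_ms, 1e-9),
                      random_state=rng)
    )
    amp = float(
        truncnorm.rvs(
            -amp_mean / max(cfg.amp_sd, 1e-9), np.inf, loc=amp_mean,
            scale=max(cfg.amp_sd, 1e-9), random_state=rng,
        )
    )
    return onset, amp, cfg.cr_rise_ms


def simulate_trace(
    plan: TrialPlan,
    session_state: tuple[float, float],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> TrialTrace:
    """Generate one trial's raw eyelid trace with ground-truth labels.

    ``session_state`` is the (p_s, amplitude_mean_s) pair from
    :func:`session_true_state`.  Raw samples are in sensor volts:
    ``baseline_volts + ur_peak_volts * (signal + drift + noise)`` where the
    signal combines the CR and UR by pointwise max (eyelid closure
    saturates) minus any photic-opening dip.
    """
    p_s, amp_mean = session_state
    if not (0.0 <= p_s <= 1.0) or not np.isfinite(amp_mean):
        raise ConfigurationError("invalid session state")
    n = int(round(cfg.trace_duration_ms * cfg.sampling_rate_hz / 1000.0))
    t = np.arange(n) * 1000.0 / cfg.sampling_rate_hz

    has_cs = plan.kind in (TrialKind.PAIRED, TrialKind.CS_ONLY)
    has_us = plan.kind in (TrialKind.PAIRED, TrialKind.US_ONLY)
    protocol_us_onset = 250.0
    cs_on = cfg.cs_onset_in_trace_ms
    us_on = cs_on + protocol_us_onset  # same absolute slot on US-only trials
    markers: dict[str, float | None] = {
        "cs_onset": cs_on if has_cs else None,
        "cs_offset": cs_on + 280.0 if has_cs else None,
        "us_onset": us_on if has_us else None,
        "us_offset": us_on + 30.0 if has_us else None,
    }
    t0 = cs_on if has_cs else us_on

    closure = np.zeros(n)
    gt: dict[str, object] = {
        "is_response": False,
        "true_amplitude": np.nan,
        "true_onset_ms": np.nan,
        "true_rise_ms": np.nan,
        "opening": False,
        "true_p": p_s,
        "true_amp_mean": amp_mean,
    }

    if has_cs and rng.random() < p_s:
        onset, amp, rise = _draw_cr_params(cfg, amp_mean, rng)
        closure = np.maximum(closure, cr_bell(t - cs_on, onset, 250.0, rise, amp))
        gt.update(
            is_response=True, true_amplitude=amp, true_onset_ms=onset, true_rise_ms=rise
        )
    if has_us:
        lat = float(np.clip(rng.normal(cfg.ur_latency_mean_ms, cfg.ur_latency_sd_ms), 5.0, 70.0))
        closure = np.maximum(
            closure, ur_pulse(t - us_on, lat, cfg.ur_rise_ms, cfg.ur_decay_ms)
        )
        gt["true_ur_latency_ms"] = lat
    opening = np.zeros(n)
    if has_cs and rng.random() < cfg.opening_prob:
        center = rng.uniform(90.0, 245.0)
        opening = _opening_dip(t - cs_on, center, cfg.opening_depth)
        gt["opening"] = True

    drift = cfg.drift_amplitude * np.sin(
        2 * np.pi * t / (cfg.drift_timescale_s * 1000.0) + rng.uniform(0, 2 * np.pi)
    )
    noise = rng.normal(0.0, cfg.noise_sigma, n) if cfg.noise_sigma > 0 else 0.0
    raw = cfg.baseline_volts + cfg.ur_peak_volts * (closure + opening + drift + noise)
    return TrialTrace(plan, raw.astype(np.float64), cfg.sampling_rate_hz, t0, markers, gt)


def simulate_session(
    plans: Sequence[TrialPlan],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    protocol: ProtocolConfig,
) -> list[TrialTrace]:
    """Simulate all trials of one session (state fixed within the session)."""
    if not plans:
        raise ConfigurationError("empty session")
    phase = plans[0].phase
    state = session_true_state(cfg, phase, plans[0].session_index + 1, protocol)
    return [simulate_trace(p, state, cfg, rng) for p in plans]


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group: label, size, and config overrides."""

    label: str
    n_subjects: int
    overrides: dict = field(default_factory=dict)
    age_range_days: tuple[float, float] = (60.0, 120.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    """A multi-group simulated experiment sharing one protocol."""

    groups: tuple[GroupSpec, ...]
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    base_config: SimulationConfig = field(default_factory=SimulationConfig)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigurationError("cohort needs at least one group")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age_days: float
    config: SimulationConfig
    seed_seq: np.random.SeedSequence


def _subject_records(spec: CohortSpec) -> list[SubjectRecord]:
    root = np.random.SeedSequence(spec.master_seed)
    children = root.spawn(sum(g.n_subjects for g in spec.groups))
    records = []
    i = 0
    for g in spec.groups:
        base = dataclasses.replace(spec.base_config, **g.overrides)
        for k in range(g.n_subjects):
            ss = children[i]
            i += 1
            rng = np.random.default_rng(ss.spawn(1)[0])
            age = float(rng.uniform(*g.age_range_days))
            # between-subject heterogeneity in learning asymptotes
            pmax = float(np.clip(rng.normal(base.p_max, base.subject_pmax_sd), 0.0, 1.0)) \
                if base.p_max > 0 else 0.0
            amax = float(max(rng.normal(base.amp_max, base.subject_amp_sd), 0.05))
            cfg = dataclasses.replace(base, p_max=pmax, amp_max=amax)
            records.append(SubjectRecord(f"{g.label}_{k:02d}", g.label, age, cfg, ss))
    return records


def _phase_sessions(protocol: ProtocolConfig) -> list[tuple[Phase, int]]:
    out = [(Phase.ACQUISITION, s) for s in range(protocol.n_acquisition_sessions)]
    out += [(Phase.EXTINCTION, s) for s in range(protocol.n_extinction_sessions)]
    out += [(Phase.REACQUISITION, s) for s in range(protocol.n_reacquisition_sessions)]
    return out


def iter_cohort_sessions(
    spec: CohortSpec,
) -> Iterator[tuple[SubjectRecord, Phase, int, list[TrialTrace]]]:
    """Stream (subject, phase, session_index, traces) without holding the
    whole cohort in memory.  Fully reproducible from ``master_seed``."""
    for rec in _subject_records(spec):
        rng = np.random.default_rng(rec.seed_seq.spawn(2)[1])
        for phase, s in _phase_sessions(spec.protocol):
            if phase is Phase.EXTINCTION:
                plans = build_extinction_schedule(spec.protocol, rng, session_index=s)
            else:
                ph = Phase.REACQUISITION if phase is Phase.REACQUISITION else Phase.ACQUISITION
                plans = build_acquisition_schedule(
                    spec.protocol, rng, session_index=s, phase=ph
                )
            yield rec, phase, s, simulate_session(plans, rec.config, rng, spec.protocol)


def ground_truth_table(spec: CohortSpec) -> pd.DataFrame:
    """Per subject/phase/session true probability and amplitude mean."""
    rows = []
    for rec in _subject_records(spec):
        for phase, s in _phase_sessions(spec.protocol):
            p, a = session_true_state(rec.config, phase, s + 1, spec.protocol)
            rows.append(
                dict(
                    subject_id=rec.subject_id,
                    group=rec.group,
                    age_days=rec.age_days,
                    phase=phase.value,
                    session=s,
                    true_probability=p,
                    true_amplitude=a,
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fast amplitude-level generative path
#
# The decomposition consumes only the per-trial peak amplitude in the CS
# window; for Monte-Carlo work at hundreds of cohort replicates the full
# 2500-sample traces are unnecessary.  This path draws the window peaks
# directly from the same mixture the trace simulator realizes: with
# probability p the (signed-extremum) peak is the CR amplitude plus smoothed
# sensor noise, otherwise it is the signed extremum of smoothed noise alone.


def simulate_peak_amplitudes(
    p: float,
    amp_mean: float,
    amp_sd: float,
    n_trials: int,
    rng: np.random.Generator,
    noise_sigma: float = 0.02,
    smooth_window: int = 10,
    window_samples: int = 150,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-trial signed window-peak amplitudes and response labels.

    Smoothing a w-sample moving average over iid noise leaves about
    ``window_samples / smooth_window`` effectively independent values of
    standard deviation ``noise_sigma / sqrt(smooth_window)`` in the
    measurement window; the non-response peak is their signed extremum.
    """
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError("p must lie in [0, 1]")
    is_resp = rng.random(n_trials) < p
    sigma_eff = noise_sigma / np.sqrt(max(smooth_window, 1))
    m = max(window_samples // max(smooth_window, 1), 1)
    noise = rng.normal(0.0, sigma_eff, size=(n_trials, m)) if sigma_eff > 0 else np.zeros((n_trials, m))
    idx = np.argmax(np.abs(noise), axis=1)
    peaks = noise[np.arange(n_trials), idx]  # signed extremum of the null
    n_resp = int(is_resp.sum())
    if n_resp:
        amps = truncnorm.rvs(
            -amp_mean / max(amp_sd, 1e-12), np.inf,
            loc=amp_mean, scale=max(amp_sd, 1e-12), size=n_resp, random_state=rng,
        )
        peaks[is_resp] = amps + rng.normal(0.0, sigma_eff, n_resp)
    return peaks, is_resp
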