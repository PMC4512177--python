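"""Monte-Carlo validation studies: estimator calibration, parameter
recovery, and phenotype-detection power.

These studies are the package's evidence that the pipeline measures what it
claims: the decomposition reports probability ~0 on pure noise and recovers
mixture parameters; the timing detectors recover generative onset/peak/rise;
the group tests hold their nominal type-I error; and cohorts built with a
generative probability or timing deficit are detected by the same battery a
conditioning study would run.

Cohort-level studies that only exercise the decomposition run on the
amplitude-level generative path (:func:`eyeblink.simulate.simulate_peak_amplitudes`),
which draws the per-trial window peaks from the same mixture the trace
simulator realizes; the timing study simulates full traces.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .decomposition import decompose_amplitudes
from .preprocess import normalize_session
from .protocol import ProtocolConfig, TrialKind, build_acquisition_schedule
from .response_metrics import cr_timing, ur_metrics
from .simulate import SimulationConfig, simulate_peak_amplitudes, simulate_trace
from .stats import rm_anova_2way, simulate_null_metric_curves, unpaired_t


def saturating_curve(p_max: float, tau: float, n_sessions: int) -> np.ndarray:
    """Closed-form learning curve p_s = p_max * (1 - exp(-s / tau))."""
    s = np.arange(1, n_sessions + 1)
    return p_max * (1.0 - np.exp(-s / tau))


# ---------------------------------------------------------------------------
# Decomposition calibration and recovery


def null_probability(
    rng: np.random.Generator, n_samples: int = 10_000, noise_sigma: float = 0.02
) -> float:
    """Estimated response probability on pure zero-mean noise (should be ~0)."""
    return decompose_amplitudes(rng.normal(0.0, noise_sigma, n_samples)).probability


def mixture_recovery(
    seed: int,
    p_values: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9),
    n_seeds: int = 20,
    n_samples: int = 1000,
    amp_mean: float = 0.4,
    amp_sd: float = 0.05,
    noise_sigma: float = 0.02,
    p_tol: float = 0.05,
    amp_tol: float = 0.03,
) -> pd.DataFrame:
    """Two-component-mixture recovery study.

    For each mixing weight p and replicate seed, draws ``n_samples`` peak
    amplitudes (response: Normal(amp_mean, amp_sd); non-response:
    Normal(0, noise_sigma)), decomposes, and records estimation errors and
    whether both fall inside the stated tolerances.
    """
    rows = []
    for p in p_values:
        for k in range(n_seeds):
            rng = np.random.default_rng([seed, int(round(1000 * p)), k])
            is_resp = rng.random(n_samples) < p
            vals = np.where(
                is_resp,
                rng.normal(amp_mean, amp_sd, n_samples),
                rng.normal(0.0, noise_sigma, n_samples),
            )
            res = decompose_amplitudes(vals)
            amp_err = (res.amplitude - amp_mean) if res.amplitude is not None else np.inf
            rows.append(
                dict(
                    p=p, replicate=k,
                    p_err=res.probability - p, amp_err=amp_err,
                    ok=abs(res.probability - p) <= p_tol and abs(amp_err) <= amp_tol,
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Timing recovery


def _probe_plans(seed: int = 1) -> tuple:
    cfg = ProtocolConfig()
    plans = build_acquisition_schedule(cfg, seed)
    plan_cs = next(p for p in plans if p.kind is TrialKind.CS_ONLY)
    plan_paired = next(p for p in plans if p.kind is TrialKind.PAIRED)
    return plan_cs, plan_paired


def cr_timing_recovery(
    rng: np.random.Generator,
    n_trials: int = 200,
    cfg: SimulationConfig | None = None,
    amplitude: float = 0.4,
) -> dict[str, float]:
    """Simulate CS-only probe trials with known CR timing and measure the
    mean estimated onset, peak latency and 10-90% rise time."""
    cfg = cfg or SimulationConfig()
    plan_cs, plan_paired = _probe_plans()
    traces = [simulate_trace(plan_paired, (0.0, amplitude), cfg, rng)]
    traces += [
        simulate_trace(plan_cs, (1.0, amplitude), cfg, rng) for _ in range(n_trials)
    ]
    trials = normalize_session(traces)
    est, tru = [], []
    for t in trials[1:]:
        if not t.valid:
            continue
        m = cr_timing(t)
        if m.is_cr and m.rise_time_10_90_ms is not None:
            est.append((m.onset_latency_ms, m.peak_latency_ms, m.rise_time_10_90_ms))
            tru.append(t.ground_truth["true_onset_ms"])
    arr = np.asarray(est)
    return {
        "n": len(est),
        "onset_mean_ms": float(arr[:, 0].mean()),
        "peak_mean_ms": float(arr[:, 1].mean()),
        "rise_mean_ms": float(arr[:, 2].mean()),
        "true_onset_mean_ms": float(np.mean(tru)),
    }


def ur_latency_recovery(
    rng: np.random.Generator, n_trials: int = 100, cfg: SimulationConfig | None = None
) -> dict[str, float]:
    """Simulate paired trials and recover the mean UR latency and rise time."""
    cfg = cfg or SimulationConfig()
    _, plan_paired = _probe_plans()
    traces = [simulate_trace(plan_paired, (0.0, 0.4), cfg, rng) for _ in range(n_trials)]
    lat, rise, tru = [], [], []
    for t in normalize_session(traces):
        if not t.valid:
            continue
        m = ur_metrics(t)
        lat.append(m.latency_ms)
        rise.append(m.rise_time_ms)
        tru.append(t.ground_truth["true_ur_latency_ms"])
    return {
        "n": len(lat),
        "latency_mean_ms": float(np.mean(lat)),
        "rise_mean_ms": float(np.mean(rise)),
        "true_latency_mean_ms": float(np.mean(tru)),
    }


# ---------------------------------------------------------------------------
# Statistical calibration


def type1_calibration(
    rng: np.random.Generator,
    n_reps: int = 1000,
    n_per_group: tuple[int, int] = (10, 10),
    n_sessions: int = 12,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Type-I error of the RM-ANOVA genotype effect and of the last-four
    unpaired t-test over null cohort simulations (no group effect)."""
    rej_anova = rej_t = 0
    for _ in range(n_reps):
        df = simulate_null_metric_curves(n_per_group, n_sessions, rng)
        res = rm_anova_2way(df)
        rej_anova += res["group"].p_value < alpha
        last4 = df[df["session"] >= n_sessions - 4].groupby(["group", "subject_id"])[
            "value"
        ].mean()
        a = last4.xs("a", level="group").to_numpy()
        b = last4.xs("b", level="group").to_numpy()
        rej_t += unpaired_t(a, b).p_value < alpha
    return {
        "rm_anova_group": rej_anova / n_reps,
        "unpaired_t": rej_t / n_reps,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# Phenotype-detection power


def probability_deficit_replicate(
    rng: np.random.Generator,
    n_per_group: int = 12,
    p_maxes: tuple[float, float] = (0.55, 0.35),
    tau: float = 4.0,
    amp_max: float = 0.45,
    n_sessions: int = 12,
    n_trials: int = 220,
    subject_pmax_sd: float = 0.05,
) -> float:
    """One simulated two-group cohort with a generative probability deficit;
    returns the RM-ANOVA genotype main-effect p-value on decomposition
    probabilities (amplitude-level generative path)."""
    rows = []
    for g, pmax in zip(("a", "b"), p_maxes):
        for i in range(n_per_group):
            pm = float(np.clip(rng.normal(pmax, subject_pmax_sd), 0.0, 1.0))
            am = float(max(rng.normal(amp_max, 0.03), 0.05))
            for s in range(1, n_sessions + 1):
                p_s = pm * (1 - np.exp(-s / tau))
                a_s = am * (1 - np.exp(-s / tau))
                peaks, _ = simulate_peak_amplitudes(p_s, a_s, 0.05, n_trials, rng)
                rows.append(
                    dict(
                        subject_id=f"{g}{i}", group=g, session=s,
                        value=decompose_amplitudes(peaks).probability,
                    )
                )
    return rm_anova_2way(pd.DataFrame(rows))["group"].p_value


def _subject_mean_rise(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    n_probe: int,
    state: tuple[float, float],
) -> float:
    plan_cs, plan_paired = _probe_plans()
    traces = [simulate_trace(plan_paired, state, cfg, rng)]
    traces += [simulate_trace(plan_cs, state, cfg, rng) for _ in range(n_probe)]
    rises = []
    for t in normalize_session(traces)[1:]:
        if not t.valid:
            continue
        m = cr_timing(t)
        if m.is_cr and m.rise_time_10_90_ms is not None:
            rises.append(m.rise_time_10_90_ms)
    return float(np.mean(rises)) if rises else np.nan


def timing_deficit_replicate(
    rng: np.random.Generator,
    n_per_group: int = 12,
    rises_ms: tuple[float, float] = (90.0, 140.0),
    onset_means_ms: tuple[float, float] = (145.0, 85.0),
    n_probe: int = 22,
    state: tuple[float, float] = (0.55, 0.42),
) -> float:
    """One simulated two-group cohort with a generative rise-time deficit;
    full trace simulation + timing detection; returns the unpaired t-test
    p-value on per-subject mean 10-90% rise times.

    The slower-rising group starts its CRs earlier (as slow-rise mutants
    do), keeping the bell geometry feasible with the peak fixed at the US.
    """
    base = SimulationConfig()
    groups = []
    for rise, onset in zip(rises_ms, onset_means_ms):
        cfg = dataclasses.replace(base, cr_rise_ms=rise, cr_onset_mean_ms=onset)
        vals = [_subject_mean_rise(cfg, rng, n_probe, state) for _ in range(n_per_group)]
        groups.append(np.asarray([v for v in vals if np.isfinite(v)]))
    return unpaired_t(groups[0], groups[1]).p_value
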