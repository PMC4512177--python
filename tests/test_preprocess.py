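"""Normalization, baseline stability, smoothing, and exclusion rules."""

import numpy as np
import pytest

from eyeblink.preprocess import (
    BaselineCriterion,
    ExclusionReason,
    ReferenceError,
    check_baseline_stability,
    early_movement_flag,
    normalize_session,
    normalize_trial,
    smooth,
)
from eyeblink.protocol import ConfigurationError, TrialKind
from eyeblink.simulate import SimulationConfig, simulate_trace

from .conftest import build_normalized, build_raw_trace, plan_of


def _paired_raw(baseline=2.0, ur_peak=3.0):
    """Flat raw trace at ``baseline`` with a triangular UR reaching
    ``ur_peak`` 50 ms after US onset (US at +250 ms from CS)."""

    def fn(t):
        y = np.full_like(t, baseline, dtype=float)
        rise = (t >= 270) & (t <= 320)
        y[rise] = baseline + (ur_peak - baseline) * (t[rise] - 270) / 50.0
        fall = (t > 320) & (t <= 370)
        y[fall] = baseline + (ur_peak - baseline) * (370 - t[fall]) / 50.0
        return y

    return build_raw_trace(fn, TrialKind.PAIRED)


class TestNormalization:
    def test_midpoint_maps_to_half(self):
        nt = normalize_trial(_paired_raw(2.0, 3.0))
        t = nt.times_ms
        # raw 2.5 occurred at t = 295 ms (halfway up the UR)
        assert nt.samples[np.searchsorted(t, 295)] == pytest.approx(0.5, abs=0.02)

    def test_ur_peak_maps_to_one(self):
        nt = normalize_trial(_paired_raw())
        assert np.max(nt.window(250, 450)) == pytest.approx(1.0)

    def test_baseline_maps_to_zero(self):
        nt = normalize_trial(_paired_raw())
        assert np.mean(nt.window(-500, -1)) == pytest.approx(0.0, abs=1e-12)

    def test_idempotent_on_normalized_paired_trial(self):
        nt = normalize_trial(_paired_raw())
        again = normalize_trial(
            build_raw_trace(lambda t: np.interp(t, nt.times_ms, nt.samples), TrialKind.PAIRED)
        )
        assert np.allclose(again.samples, nt.samples, atol=1e-9)

    def test_affine_invariance(self):
        a = normalize_trial(_paired_raw(2.0, 3.0))
        b = normalize_trial(_paired_raw(7.5, 12.5))  # gain 5, offset -2.5
        assert np.allclose(a.samples, b.samples, atol=1e-9)

    def test_cs_only_without_reference_invalid(self):
        tr = build_raw_trace(lambda t: np.full_like(t, 2.0), TrialKind.CS_ONLY)
        nt = normalize_trial(tr, last_paired_ur_range=None)
        assert not nt.valid
        assert nt.exclusion_reason is ExclusionReason.NO_UR_REFERENCE

    def test_degenerate_reference_marks_invalid_without_raising(self):
        tr = build_raw_trace(lambda t: np.full_like(t, 2.0), TrialKind.PAIRED)
        nt = normalize_trial(tr)  # UR peak == baseline
        assert not nt.valid
        assert nt.exclusion_reason is ExclusionReason.DEGENERATE_REFERENCE

    def test_session_carries_most_recent_paired_reference(self):
        tr1 = _paired_raw(2.0, 3.0)  # range 1.0
        tr2 = _paired_raw(2.0, 4.0)  # range 2.0
        probe = build_raw_trace(lambda t: 2.0 + 0.5 * (np.abs(t - 200) < 20), TrialKind.CS_ONLY)
        out = normalize_session([tr1, tr2, probe])
        # probe's 0.5 V bump scaled by the *second* trial's 2.0 V range
        assert np.max(out[2].window(100, 280)) == pytest.approx(0.25, abs=0.02)

    def test_first_probe_in_session_is_skipped(self):
        probe = build_raw_trace(lambda t: np.full_like(t, 2.0), TrialKind.CS_ONLY)
        out = normalize_session([probe, _paired_raw()])
        assert not out[0].valid and out[1].valid


class TestSmoothing:
    def test_constant_maps_to_itself(self):
        x = np.full(500, 3.3)
        assert np.allclose(smooth(x, 10.0), x)

    def test_impulse_becomes_plateau(self):
        x = np.zeros(201)
        x[100] = 5.0
        y = smooth(x, 10.0)
        assert y.max() == pytest.approx(0.5)  # h/k with k=10
        assert np.sum(y > 0.49) == 10

    def test_output_length_preserved_and_noise_reduced(self, rng):
        t = np.linspace(0, 1, 1000)
        clean = t * 0.4
        noisy = clean + rng.normal(0, 0.02, t.size)
        y = smooth(noisy, 10.0)
        assert y.size == noisy.size
        assert np.sqrt(np.mean((y - clean) ** 2)) < np.sqrt(np.mean((noisy - clean) ** 2))

    def test_kernel_wider_than_trace_rejected(self):
        with pytest.raises(ConfigurationError):
            smooth(np.zeros(5), 10.0)


class TestEarlyMovement:
    def test_excursion_above_threshold_flags(self):
        nt = build_normalized(lambda t: 0.06 * ((t >= 45) & (t <= 55)))
        assert early_movement_flag(nt) is True

    def test_quiet_window_not_flagged(self):
        nt = build_normalized(lambda t: 0.04 * ((t >= 0) & (t <= 99)))
        assert early_movement_flag(nt) is False

    def test_boundary_is_strict(self):
        nt = build_normalized(lambda t: 0.05 * ((t >= 40) & (t <= 60)))
        assert early_movement_flag(nt) is False  # 0.05 exactly -> not flagged


class TestBaselineStability:
    def test_flat_segment_stable(self):
        stable, ext = check_baseline_stability(np.zeros(3000), BaselineCriterion(), 1.0)
        assert stable and ext == 0

    def test_early_transient_with_quiet_final_window(self):
        seg = np.zeros(3000)
        seg[:1000] = 0.2  # excursion ending 2 s before the planned CS
        stable, _ = check_baseline_stability(seg, BaselineCriterion(), 1.0)
        assert stable

    def test_persistent_oscillation_unstable(self):
        t = np.arange(3000)
        seg = 0.15 * np.sign(np.sin(2 * np.pi * t / 200))
        stable, ext = check_baseline_stability(seg, BaselineCriterion(), 1.0)
        assert not stable
        assert ext >= 1

    def test_extension_count_finds_first_quiet_window(self):
        t = np.arange(1500)
        noisy = 0.3 * np.sign(np.sin(2 * np.pi * t / 100))
        seg = np.concatenate([noisy, np.zeros(1500)])
        stable, ext = check_baseline_stability(seg, BaselineCriterion(), 1.0)
        assert stable  # final 1 s window is quiet
        assert ext == 2  # windows ending at 1 s and 2 s still catch the noise

    def test_nonpositive_ur_reference_rejected(self):
        with pytest.raises(ReferenceError):
            check_baseline_stability(np.zeros(2000), BaselineCriterion(), 0.0)


class TestSimulatedTraceNormalization:
    def test_simulated_paired_trial_normalizes_to_unit_ur(self, rng):
        cfg = SimulationConfig(noise_sigma=0.0, drift_amplitude=0.0, opening_prob=0.0)
        tr = simulate_trace(plan_of(TrialKind.PAIRED), (0.0, 0.4), cfg, rng)
        nt = normalize_trial(tr)
        assert np.max(nt.window(250, 450)) == pytest.approx(1.0, abs=1e-9)
        assert abs(np.mean(nt.window(-500, -1))) < 1e-9


class TestSessionAverageNormalization:
    def test_equivalent_session_metrics(self, rng):
        """Per-trial and session-average UR normalization should give
        indistinguishable decomposition metrics on a stable session."""
        from eyeblink.decomposition import session_metrics
        from eyeblink.protocol import ProtocolConfig, build_acquisition_schedule
        from eyeblink.simulate import SimulationConfig, simulate_session

        cfg = SimulationConfig(opening_prob=0.0)
        plans = build_acquisition_schedule(ProtocolConfig(blocks_per_session=8), rng)
        proto = ProtocolConfig()
        traces = simulate_session(
            [p for p in plans], cfg, rng, proto
        )
        m1 = session_metrics(normalize_session(traces, mode="per_trial"))
        m2 = session_metrics(normalize_session(traces, mode="session_average"))
        assert m1["probability"] == pytest.approx(m2["probability"], abs=0.06)
        assert m1["amplitude"] == pytest.approx(m2["amplitude"], abs=0.04)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            normalize_session([_paired_raw()], mode="bogus")

    def test_ur_velocity_tracks_magnitude(self, rng):
        """With a session-wide scale, UR peak velocity is proportional to UR
        magnitude (slope ~ 1/rise time)."""
        from eyeblink.response_metrics import ur_metrics

        def make(amp):
            def fn(t):
                u = t - 250.0
                y = np.clip((u - 20.0) / 40.0, 0.0, 1.0) * amp
                return 2.0 + y  # volts, baseline 2.0

            return build_raw_trace(fn, TrialKind.PAIRED)

        amps = np.linspace(0.6, 1.4, 9)
        trials = normalize_session([make(a) for a in amps], mode="session_average")
        mags, vels = [], []
        for t in trials:
            m = ur_metrics(t)
            mags.append(m.peak_amplitude)
            vels.append(m.peak_velocity)
        slope = np.polyfit(mags, vels, 1)[0]
        assert slope == pytest.approx(1.0 / 40.0, rel=0.15)
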