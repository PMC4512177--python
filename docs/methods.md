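# Methods

## The measurement problem

Delay eyeblink conditioning pairs a 280 ms light CS with a 30 ms corneal
airpuff US that co-terminates with it (US onset 250 ms after CS onset).
With training, mice produce an anticipatory eyelid closure (CR) that peaks
near the expected US time.  The classical "%CR" measure — the fraction of
trials whose eyelid displacement exceeds a fixed threshold (0.15 of the
reflex-blink amplitude) — conflates two distinct quantities: how *often* an
animal responds and how *large* its responses are.  This package implements
a session-level decomposition that separates them, together with the trial
preprocessing, response-timing detectors, and cohort statistics needed to
compare groups, and a generative trace simulator that provides ground truth
for every estimator.

## Probability/amplitude decomposition by histogram reflection

For each session, the per-trial peak normalized eyelid amplitude is
collected in a CS measurement window (default 100–250 ms after CS onset on
paired trials, stopping at the US so the reflex cannot contaminate the
peak; 100–280 ms on CS-only probes, which have no US).  The peak is the
*signed extremum* — the value of greatest displacement, keeping its sign —
so photic eyelid openings populate negative bins.  Amplitudes are histogrammed
with bin width 0.025, tiled so one bin spans exactly [−0.0125, +0.0125].

Trials without a response scatter symmetrically about zero (sensor noise
moves the lid either way), so the negative half of the histogram, its
mirror image across zero, and the zero-centered bin together estimate the
non-response ("failure") distribution.  Then

* failure rate = non-response mass / total trials (clamped to [0, 1]);
* **probability** = 1 − failure rate;
* **amplitude** = center of mass of the response distribution that remains
  after subtracting the reflected failure distribution from the positive
  side, with per-bin mass floored at zero.

### Amplitude noise mask

Per-bin flooring `max(pos − reflected, 0)` has strictly positive
expectation wherever the reflected count is nonzero, even when the true
response mass there is zero.  When responses are rare this residual sits in
low-amplitude bins and drags the center of mass toward zero (measured bias
≈ −0.04 at mixing weight 0.1 with raw noise SD 0.02, n = 1000).  The
amplitude therefore ignores bins whose floored mass does not exceed
2·√(2·reflected) — a conventional 2σ cut on the counting noise of the
subtraction.  Bins with no reflected mass are never masked, so the rule is
inert wherever the failure distribution has no support.  `noise_mask_z=0`
restores the plain floored center of mass.  The probability estimate is
untouched by this rule.

### Boundary and tie conventions

All threshold comparisons are strict (`>` / `<`); time windows are closed
on both ends, in ms from CS onset (US-only trials: from US onset).  The
zero-centered bin belongs wholly to the non-response mass.  Peak searches
resolve at the sample interval with ties broken toward the earliest time.
Probability and failure rate are clamped to [0, 1]; the amplitude is
undefined (reported as missing) when no response mass survives.

## Preprocessing

* **Normalization.**  Each paired trial is scaled so its pre-CS baseline
  (mean of the 500 ms before CS onset) maps to 0 and its own UR peak (raw
  maximum within 200 ms after US onset) maps to 1.  CS-only probes use the
  UR range (peak − baseline) of the most recent preceding paired trial; a
  probe with no prior paired trial in the session is marked invalid and
  skipped.  Normalization is invariant to gain/offset changes of the raw
  signal, and idempotent on already-normalized trials.  A session-wide
  average-UR normalization is available as a config option for equivalence
  checks.
* **Baseline stability / adaptive ITI.**  A trial may begin only after at
  least 12 s have elapsed and every sample of the final 1 s pre-CS window
  stays within ±10% of the average UR amplitude around the window median;
  each violation defers the trial by 1 s.  The checker returns both the
  verdict and the number of 1 s extensions needed, for use in scheduling
  loops.
* **Smoothing.**  Zero-phase moving average, default 10 ms, edge-padded so
  constants map to themselves.  All scoring and timing rules operate on
  smoothed traces; at 1 kHz with sensor noise SD 0.02 the raw trace would
  trip the early-movement rule on roughly half of all trials.
* **Early-movement exclusion.**  Probe trials whose smoothed response
  exceeds 0.05 between 0 and 99 ms after CS onset are excluded from CR
  scoring and timing.  By default the rule is not applied to the
  decomposition input (the histogram absorbs such trials symmetrically); a
  config flag extends it to all trials.

## Response detection and timing

A CS-only probe scores as a **CR** when its smoothed trace exceeds 0.15
between 100 and 400 ms after CS onset (and survives the early-movement
rule).  For scored CRs:

* **peak latency** — argmax of the smoothed trace in the scoring window;
* **onset latency** — the change of concavity before the rise,
  operationalized as the latest ≤0→>0 transition of the Savitzky–Golay
  second derivative (25 ms window, quadratic) before the 10%-of-peak
  crossing.  Two corrections make this accurate on noisy traces: brief
  negative dips inside the curvature transient (smoothed-noise sign flips)
  are closed before runs are extracted, and the known half-width of the
  combined zero-phase kernels — which advances the leading edge of any
  transient by exactly that amount — is added back, capping at the crossing
  time.  If no qualifying transition exists the detector falls back to the
  5%-of-peak crossing and flags the trial.
* **10–90% rise time** — time between the linearly interpolated 0.1·peak
  and 0.9·peak crossings after onset.

**UR metrics** (latency, 10–90% rise, peak velocity) use the same detectors
referenced to US onset, with the onset required within 75 ms of the US.
**Photic eyelid openings** — non-associative negative deflections to the
light CS — are counted when the trace dips more than 5% below baseline
70–250 ms after CS onset, with no such dip earlier in the trial, and only
in sessions that have produced no CRs yet.

Measured recovery on simulated cohorts (200 trials, defaults): CR onset
within ~2 ms of the generative mean, peak latency within ~1 ms, rise time
within ~2 ms; UR latency within ~2 ms of its generative mean.

## Group statistics

Learning curves are per-subject, per-session (probability, amplitude, %CR)
sequences; end-of-training summaries average the last four sessions.  The
battery: unpaired two-sample t-tests with Cohen's d′ (pooled Bessel-corrected
SD — for equal n, |t| = d′·√(n/2) exactly); paired t-tests for the
extinction (last acquisition vs last extinction session) and savings (last
extinction vs last reacquisition) contrasts; one-way ANOVA with
Bonferroni-adjusted *planned* comparisons (raw p × number of planned pairs,
capped at 1); a mixed-design two-way RM ANOVA (genotype between subjects,
session within, both categorical) computed from closed-form balanced sums
of squares with uncorrected F/df (no sphericity correction), cross-checked
against an independent implementation in the test suite; and ANCOVA with
age (days) as a linear covariate followed by Tukey HSD on age-adjusted
values (with a constant covariate this reduces to the one-way ANOVA).
Subjects missing sessions are excluded listwise with a warning; nothing is
imputed.

## The generative simulator

The simulator emulates the experiment, not any particular animal:

* **Protocol.**  220-trial sessions in 22 blocks of 10 — 9 paired + 1
  CS-only probe per block during acquisition/reacquisition, the probe slot
  drawn uniformly per block from a seeded generator; 5 CS-only + 5 US-only
  per block during extinction.  12/4/3 daily sessions by default.
* **Traces.**  1 kHz sampling (the acquisition hardware band-pass is
  reported, not the digitization rate; configurable), 2.5 s duration with
  CS onset at 1.0 s, leaving the full 1 s baseline-criterion window.  Raw
  volts = baseline + UR-scale × (signal + drift + noise), with iid Gaussian
  sensor noise (SD 0.02 normalized), a slow sinusoidal drift (amplitude
  0.03, period 20 s, random phase), and a raised-cosine photic-opening dip
  (probability 0.05/trial, depth 0.12, center 90–245 ms post-CS) —
  opening amplitudes of ~6–16% of the UR match what naive animals show.
* **CR waveform.**  A monotone-PCHIP bell through (onset, 0), (t10, 0.1·A),
  (t90, 0.9·A), (peak, A), decaying as its mirror image.  This makes onset
  latency, peak time, and 10–90% rise *independently* controllable — a
  fixed-shape bell (e.g. raised cosine) cannot satisfy an arbitrary
  onset/peak/rise triple.  Defaults: onset ~ Normal(145, 10) ms, truncated
  so rise ≤ 0.92·(peak − onset) keeps the geometry feasible; peak at the
  US onset (250 ms); rise 90 ms; amplitude ~ Normal(session mean, 0.05)
  truncated at 0.
* **UR waveform.**  Latency ~ Normal(30, 5) ms after the US, linear rise to
  the raw UR peak over 80 ms (10–90% ≈ 64 ms, matching reported reflex rise
  times), exponential decay (τ = 150 ms).  CR and UR combine by pointwise
  max — eyelid closure saturates — so the UR normalization scale is not
  inflated by a decaying CR on paired trials.
* **Learning dynamics.**  Saturating exponentials in the 1-based session
  index: p_s = p_max·(1 − e^(−s/τ)) with τ = 4 sessions (and analogously
  for amplitude, asymptote 0.45).  Wild-type-like p_max = 0.55 reproduces
  end-of-training probabilities near 0.5; deficit groups lower p_max,
  amplitude, or alter CR timing.  Extinction decays the end-of-acquisition
  probability with τ = 1.2 sessions (<10% of the learned level remains by
  extinction session 4); reacquisition re-runs the acquisition curve with a
  4-session head start (savings).  Between-subject heterogeneity: p_max SD
  0.05, amplitude SD 0.03, truncated to valid ranges.
* **Seeding.**  A cohort is fully reproducible from one master seed;
  subject streams are spawned deterministically from it.

One documented protocol ambiguity: the source protocol's summary text
describes extinction as 110 CS-only + 110 US-only trials *over four
sessions*, while its procedure section specifies 22 blocks × (5 + 5) per
session — i.e., 110 + 110 *per session*.  The scheduler follows the
procedure section.

### The amplitude-level fast path

Monte-Carlo studies that exercise only the decomposition (type-I
calibration at 1000 cohorts, probability-deficit power at 200) draw the
per-trial window peaks directly from the trace model's implied mixture:
with probability p_s a truncated-normal CR amplitude plus smoothed-noise
error, otherwise the signed extremum of the smoothed noise in the window
(≈ 15 effectively independent values of SD 0.02/√10 after the 10 ms moving
average).  A dedicated test verifies the fast path and the full trace path
give compatible decompositions under identical generative conditions.  The
timing-deficit power study and all timing-recovery studies always simulate
full traces.

## What the simulator does and does not establish

Passing recovery tests shows the estimators are consistent and calibrated
*under this generative model*: symmetric sensor noise, stable UR scale,
bell-shaped CRs with a single peak, stationary per-session response
probability.  Real eyelid data can violate each assumption — asymmetric
movement noise breaks the reflection premise, multi-component blinks break
single-peak timing, within-session learning breaks stationarity — so these
results validate the arithmetic and the detectors, not the model of any
animal.  No attempt is made to reproduce published group values from real
cohorts: those datasets are not publicly deposited, and the statistics
here are validated by calibration and power on synthetic cohorts instead.

## Problem sizes

Defaults used by the validation studies (and the acceptance script): null
calibration at 10,000 samples; mixture recovery at n = 1000 × 5 mixing
weights × 20 replicates; timing recovery at 200 probe trials; type-I
calibration at 1000 null cohorts of 10 + 10 subjects × 12 sessions;
phenotype-detection power at 200 replicates of 12 + 12 subjects (full
12-session cohorts for the probability contrast, one 22-probe session per
subject for the timing contrast).  These sizes give Monte-Carlo standard
errors comfortably below the decision margins they feed.
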