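# eyeblink

Analysis pipeline for delay eyeblink conditioning in head-fixed mice:
trial-level preprocessing, separation of learned-response **probability**
from response **amplitude** by histogram reflection, conditioned/unconditioned
response timing, and the cohort statistics used to compare genotypes —
together with a generative eyelid-trace simulator that provides ground
truth for every estimator.

It is written for behavioral neurophysiologists analyzing eyelid-position
time series from conditioning rigs (and for anyone validating such
analyses on synthetic data).

## The statistic at the core

In delay conditioning a 280 ms light CS co-terminates with a 30 ms airpuff
US (US onset 250 ms after CS onset); trained animals close the eyelid in
anticipation, peaking at the expected US time.  The classical measure,
%CR = fraction of trials whose normalized eyelid peak exceeds 0.15,
conflates how *often* an animal responds with how *large* the responses
are.  Instead, for every session we histogram the per-trial peak
amplitudes x_i (normalized so baseline = 0 and the reflex-blink peak = 1)
in the CS window, with a bin centered on zero.  Non-responding trials
scatter symmetrically about zero, so with N(c) the counts in bin c:

    failure rate  F = [ N(0-bin) + Σ_{c<0} N(c) + Σ_{c<0} N(c) mirrored ] / N_total
    probability   P = 1 − F
    amplitude     A = center of mass of { N(c) − N(−c) }⁺ over c > 0

P estimates the fraction of trials with *any* CS-evoked response; A
estimates the mean size of a response *given that one occurred*.  The
package also computes CR timing from unpaired CS probe trials — onset
latency (change of concavity), peak latency, 10–90% rise time — UR latency
and rise time within 75 ms of the US, photic eyelid openings (>5% below
baseline, 70–250 ms post-CS), and a statistics battery: last-four-session
t-tests with Cohen's d′, mixed-design repeated-measures ANOVA (genotype ×
session), one-way ANOVA with Bonferroni planned comparisons, ANCOVA with
age + Tukey HSD, and paired extinction/savings contrasts.

## Worked example

Simulate one 220-trial mid-training session in which half the trials carry
a CR of mean amplitude 0.4, then decompose it:

```
$ python analysis/02_decomposition_example.py
session of 220 analyzable trials (105 carry a generative CR -> true probability 0.477)
  failure rate      0.518
  probability       0.482
  amplitude         0.379  (generative mean 0.4)
  %CR (0.15 cut)    47.7
figure: results/decomposition_example.png
```

The decomposition recovers the generative response probability (0.482 vs
0.477 true) and amplitude (0.379 vs 0.40) from the amplitude histogram
alone, without any per-trial threshold; the figure shows the histogram,
the reflected failure distribution, and the remaining response
distribution with the 0.15 threshold overlaid for comparison.

The numbered drivers under `analysis/` run the full demonstration study:

1. `01_simulate_cohort.py` — simulate and analyze a wild-type-like vs
   probability-deficit cohort (n = 5/5, 12 acquisition + 4 extinction + 3
   reacquisition sessions); writes per-session and per-trial metric tables.
2. `02_decomposition_example.py` — the histogram-reflection figure above.
3. `03_response_timing.py` — CR onset/peak/rise and UR latency summaries.
4. `04_group_stats.py` — the comparison battery and learning-curve figure.
5. `05_validation.py` — reduced Monte-Carlo validation (calibration,
   recovery, power) to `results/validation.json`.

The same pipeline is scriptable via the CLI (`eyeblink simulate|analyze|
compare|report`) with a YAML run configuration; outputs are delimited text
tables whose headers carry a schema version and a hash of the
configuration that produced them.

## Scope

The package analyzes (and simulates) eyelid traces; it does not interface
with acquisition hardware, process eye videos, or attempt to reproduce
published group values from real animal cohorts, whose raw data are not
publicly deposited.  Histology, gait, and maze assays that often accompany
conditioning studies are out of scope.
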