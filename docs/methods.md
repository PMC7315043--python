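# Methods

## Model

The analysis treats the singing dyad as one system.  The two onset streams
are merged; the inter-onset intervals (IOIs) of the merged stream are the
signal.  The score guarantees exactly three IOI duration classes (eighth,
quarter, dotted-quarter; ratio 1:2:3), so the dyad's timing state is
summarized by three latent class-duration beliefs rather than one global
tempo.  Tracking the classes separately tolerates expressive shortening or
lengthening of individual classes and follows gradual tempo change, while
staying far simpler than a coupled-tempo or particle-filter model — full
posterior distributions and credible intervals are out of scope by design.

All tracking happens in log2(duration in s).  The log domain makes
proportional errors symmetric (halving and doubling are ±1), makes the
1:2:3 class grid translation-invariant under tempo change, and makes the
natural residual exactly the proportional error log2(measured/predicted).
Millisecond errors are derived from the same prediction for reporting.

### Sequential update

Beliefs are normal-mean summaries: class c keeps mean μ_c, spread σ_c and a
trailing evidence window of time-stamped log2 durations.

* **Initialization**: k-means, k = 3, on the log2 durations of the IOIs
  completing within the first 15 s of the trial (minimum 3 IOIs, otherwise
  an insufficient-data error).  Centers map to SHORT/MID/LONG by ascending
  mean; σ_c is the cluster sample SD, floored (below).  If the init window
  is degenerate (fewer than three distinct durations, or an empty cluster),
  the fallback centers the exact 1:2:3 grid on the median init-window IOI
  and warns — this keeps pathological trials processable.
* **Assignment**: nearest belief mean in log2; ties break to the shorter
  class for determinism.  The assignment rule mirrors the error metric (the
  class whose prediction the IOI violates least).
* **Collapse test, before updating**: an IOI assigned to LONG whose log2
  duration exceeds μ_L + 2·σ_L (strict) is a breakdown gap.  The test is
  one-sided: collapses are silences where onsets were expected; abnormally
  *short* intervals are near-simultaneous singing and are handled by the
  ingest-stage simultaneity flag instead.  Collapse IOIs are recorded but
  never update any belief — a multi-second gap would wreck the LONG mean.
* **Update**: entries older than 15 s are evicted, the new value appended,
  and the posterior mean is the pseudo-count blend
  μ ← (k·μ_prior + n·x̄_window)/(k + n), k = `prior_strength` (default 5).
  This is the conjugate normal-mean update with known spread, the simplest
  form in which the prior is the mean of old predictions and the posterior
  the mean updated by the evidence window.  σ_c is the window sample SD.
  The evidence window is trailing (causal), matching a step-by-step
  sequential pass.
* After every update the three means are checked for strict S < M < L
  ordering; a violation re-sorts labels with a warning.  IOIs inside the
  init window parameterize the init and are not scored; the trace starts at
  the first IOI after 15 s.

Tunable parameters, all in `TrackerConfig` / `IOIClassTracker`:

| parameter | default | unit | role |
|---|---|---|---|
| `init_window_s` | 15 | s | k-means initialization span |
| `evidence_window_s` | 15 | s | trailing likelihood window |
| `collapse_sd_mult` | 2.0 | σ | gap threshold above the LONG mean |
| `sd_floor` | 0.02 | log2 | minimum belief spread |
| `prior_strength` | 5 | pseudo-counts | prior inertia vs window mean |
| `adapt` | True | – | False freezes beliefs at init (ablation) |

The `sd_floor` (0.02 log2 units ≈ 1.4% duration) prevents a zero-variance
collapse threshold on noise-free input and caps the tracker's certainty at
roughly the precision of onset annotation.  `prior_strength = 5` weights the
prior like five window observations: small enough to track a tempo ramp with
negligible lag, large enough to damp single-IOI excursions.

### Markers

* **Fluctuation**: RMSE of the log2 residuals per assigned class over
  non-collapse IOIs, averaged over the classes that occurred (classes with
  no scored IOI are excluded with a warning).  Under i.i.d. multiplicative
  jitter 2^N(0, σ²) the statistic estimates σ, slightly inflated by belief
  estimation noise (a few percent at realistic window sizes).
* **Narration**: a greedy single-pointer score follower aligns the observed
  assigned-class stream to the expected class sequence.  On a mismatch it
  weighs an omission hypothesis — the observed IOI merges the next two
  expected notes; legal when the observed class is the nearest class to the
  merged duration (sums above 3 eighth-units have no exact class) — against
  a substitution, chosen by which realigns the next few symbols better.
  The disambiguation lookahead (default 8 symbols) replays the follower's
  own moves recursively, which keeps clustered omissions from derailing the
  alignment; a minimal edit-distance alignment is available as
  `method="edit"`.  Ties prefer substitution.  Collapse records consume one
  expected position unscored (the gap subsumes a scheduled note), and the
  unscored init-window IOIs advance the pointer as an unscored prefix so
  the alignment starts anchored.  Matching % = 100·matched / scored observed
  IOIs (observed count as denominator; the expected count is a documented
  alternative the follower makes easy to add).
* **Collapse**: 100·collapses / all scored IOIs (collapses included in the
  denominator).

### Movement

Per force plate the channel with the largest peak-to-peak amplitude (after
mean removal) is analyzed with a continuous wavelet transform — complex
Morlet `cmor1.5-1.0` (bandwidth 1.5, center frequency 1.0), 64 scales
log-spaced over 0.25–5 Hz, the band where body sway lives.  The band with
the highest time-averaged |coefficient| summarizes the plate; the couple
magnitude is the mean of the two plates; the trial is *moving* iff that mean
is strictly above the threshold (default 25).

Absolute CWT magnitudes depend on wavelet family, scale count and
normalization, so magnitudes are amplitude-calibrated: each scale is divided
by the transform's measured response to a unit-amplitude reference sinusoid
at that scale's frequency (cached per sample rate).  A pure sway of sensor
amplitude A then scores ≈ A, which places the threshold on the same 0–127
scale as the MIDI-valued sensor data; the threshold and wavelet settings
remain configurable for recalibration under other conventions.  The sensor
sample rate is never guessed — it must be supplied (the simulator uses
20 Hz, comfortably above Nyquist for the 5 Hz band edge).

### Exclusions and correlations

A trial is excluded when movement is detected in a non-movement trial, or
when the fraction of IOIs shorter than a validity floor (default: half the
nominal eighth-note duration, else 0.1 s) exceeds 10% — near-simultaneous
singing that the hocket task forbids.  Exact onset ties across singers are
dropped at merge time (zero IOIs would break log2 errors) and count toward
that fraction.

Marker-rating association uses Kendall's tau-b with tie correction and a
two-sided p-value: agency is a 7-point Likert scale and quality means are
heavily tied, so a tie-corrected rank statistic is required.  The per-trial
quality scalar is the time-average of the two raters' mean trace (mean
rather than peak; configurable by reducing the trace differently).  The
annotation slider's reaction lag relative to the performance is not
corrected.  Inferential group comparisons (mixed ANOVA, signed-rank tests)
are deliberately out of scope; the exported tidy tables feed external
statistics software.

## Synthetic dyad generator

The generator walks the expected class sequence of a two-part score (the
bundled 16-note toy score spans both parts and all three classes, 9 S : 5 M
: 2 L per repeat, mostly alternating voices) and draws each IOI as
nominal(current tempo) · 2^N(0, jitter²).  Error injections mirror the
marker taxonomy: substitutions replace a note's class by a uniformly
different one; omissions delete an interior onset so two IOIs merge;
collapse gaps add U(2, 8) s (configurable) to an IOI.  Onsets are attributed
to singers by the score's part column, and omissions remove the scheduled
singer's onset, preserving the merged-stream semantics.  Tempo can be fixed,
ramp linearly (bpm per minute) or follow a random walk.  Every injection is
recorded with its position in a ground-truth object, so recovery tests count
events exactly.

Defaults describe one plausible 2-minute trial: 120 bpm, 19 repeats of the
toy score (303 IOIs — near the ~319 theoretical IOIs of a 2-minute
performance of the study melody), jitter σ = 0.05 log2 units (≈3.5% of an
IOI, between the observed expert and non-expert fluctuation levels),
p_omit = 0.02, p_substitute = 0.03, p_collapse = 0.01.  Collapse gaps are
only injected at IOIs starting after a 20-s settle period so that every gap
lands in the tracker's scored region and truth-vs-detected matching is
positional; `n_collapse_events` draws an exact number of gap positions when
a test needs a fixed count.  Sensors are sinusoidal sway (plus a small
second harmonic and noise, channel gains 1.0/0.7/0.5/0.3, quantized around
MIDI 64) or noise only; annotations are two raters' slider traces decreasing
affinely in the local injected-error density, clipped to [0, 127], starting
at the neutral 64; agency ratings decrease with the overall injected error
rate.  The cohort generator spreads duo "skill" over [0, 1] and scales all
error rates with it, which builds in the monotone marker-rating links.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: mutual adaptation between the singers (both voices
ride one stochastic clock), pitch and timbre, onset-detection artifacts,
annotation lag, and rater idiosyncrasies beyond i.i.d. noise.  Recovery
results on this test bed validate the estimator pipeline, not the
psychological model.

## Numerical choices and degenerate inputs

Seeded `numpy` generators everywhere; k-means uses a fixed `random_state`
and 10 restarts; identical inputs and seeds give identical traces, and the
CLI writes with fixed float formatting so reruns are byte-identical.
Classification ties go to the shorter class; the collapse boundary is
strict (exactly μ + 2σ is not a collapse); the movement boundary is strict
(exactly 25 is still).  Annotation series that are not exactly 1000 samples
are linearly resampled with a warning; unsorted or duplicate onset rows are
format errors naming the row; an all-collapse trace raises an
undefined-metric error rather than reporting fluctuation = 0.

## Validation problem sizes

The test suite and `scripts/acceptance.py` run entirely on the generator:
trials of 8–32 score repeats (≈130–511 IOIs), 3–20 seeds per property, a
40-trial movement batch, 100 random vectors (n ≤ 50) for the tau oracle and
a 32-trial cohort for the correlation sign pattern — sizes chosen to hold
Monte-Carlo error a factor below each asserted tolerance.

## Known limitations

* The 2-SD gap rule is a statistical outlier test: under heavy jitter it
  also flags extreme slow LONG outliers that were not injected as gaps
  (visible in the README example).  This is inherent to the rule, not a
  detection bug; completeness is exact on clean performances.
* The narration follower is greedy; pathological error bursts can still
  cost extra mismatches relative to a globally optimal alignment (the
  edit-distance option bounds that gap).
* Under a *rising* tempo ramp a frozen-prior ablation degrades fluctuation
  but not narration: the ≈0.14 log2 shift of a 10% tempo change stays well
  inside the 0.29 half-distance between the MID and LONG class means, so
  classification — and with it narration matching — is unaffected.  Only
  larger tempo excursions (ratio > 2^0.29 ≈ 1.22) or falling ramps (which
  push LONG IOIs over the collapse threshold) separate the ablation on
  narration.
* The movement threshold is only meaningful relative to the calibration
  convention; changing wavelet settings requires recalibrating it.
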