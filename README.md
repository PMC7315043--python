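# dyadtiming

Objective timing markers of interaction quality for two singers performing a
semi-hocket melody — one melody split over two voices that alternate notes, so
that the dyad, not either individual, produces a single rhythmic stream.

`dyadtiming` is written for researchers in joint-action / music-performance
timing who have per-singer note-onset lists (plus, optionally, continuous
quality annotations, joint-agency ratings and force-plate traces) and want
per-trial, dynamics-aware error markers instead of a single global tempo fit.

## The method

Both singers' onsets are merged into one stream; successive differences form
the **relative inter-onset intervals (IOIs)**, whoever sang the delimiting
onsets.  The score uses exactly three IOI classes — eighth, quarter and
dotted-quarter notes, durations in ratio 1:2:3.

The dyad is modelled as maintaining a latent belief about each class's
current duration.  Working in log2(duration), with per-class belief mean
μ_c and spread σ_c:

1. **Init** — k-means (k = 3) on the log2 durations of all IOIs in the first
   15 s of the trial; centers map to SHORT/MID/LONG by ascending mean.
2. **Assign** — each incoming IOI of duration *d* goes to the class
   minimising |log2 *d* − μ_c| (ties to the shorter class).
3. **Collapse test** — if the assigned class is LONG and
   log2 *d* > μ_L + 2 σ_L, the IOI is a breakdown gap: it is recorded but
   never enters any evidence window.
4. **Score** — otherwise the proportional prediction error is
   ε = log2(*d* / 2^μ_c), also reported as 1000·(*d* − 2^μ_c) ms.
5. **Update** — the class belief folds the observation into a trailing 15-s
   evidence window and takes the conjugate normal-mean posterior
   μ ← (k·μ_prior + n·x̄_window)/(k + n) with pseudo-count k (default 5);
   σ_c is the window SD (floored).  Because each class tracks its own
   duration, gradual tempo change is followed without a global tempo model.

Each trial reduces to three markers:

* **fluctuation** — micro-timing: RMSE of ε per class, averaged over classes
  (log2 units);
* **narration** — meso-timing: % of IOIs whose assigned class matches the
  score expectation, after a score follower aligns the observed stream to
  the expected class sequence (absorbing omissions as merged IOIs);
* **collapse** — macro-timing: % of IOIs flagged as breakdown gaps.

Alongside the tracker the package provides a wavelet movement classifier
(continuous Morlet wavelet transform of the liveliest force-plate channel,
0.25–5 Hz band, couple-mean magnitude, strictly-above-25 decision rule on
amplitude-calibrated magnitudes), protocol-violation trial exclusion
(movement during non-movement trials; near-simultaneous singing), Kendall
tau-b correlations of the markers against mean quality and agency ratings,
and a full synthetic dyad simulator with ground truth for every injected
error.

## Worked example

```python
import dyadtiming as dt
from dyadtiming.simulate import SimConfig

cfg = SimConfig(jitter_sigma_log2=0.04, p_omit=0.01, p_substitute=0.05,
                p_collapse=0.01, seed=42)
a, b, truth = dt.render_performance(cfg)
series = dt.merge_onsets(a, b)
tracker = dt.IOIClassTracker().fit(series)
expected = dt.expected_class_sequence(cfg.resolved_score, cfg.n_repeats)
summary = dt.summarize_trace(tracker.trace_, expected,
                             prefix_classes=tracker.init_assigned_)
print(f"IOIs scored:        {summary.n_iois}")
print(f"fluctuation RMSE:   {summary.fluctuation_rmse_mean:.4f}  (log2 units)")
print(f"narration matching: {summary.narration_matching_pct:.1f} %")
print(f"collapse:           {summary.collapse_pct:.2f} %  ({summary.n_collapses} gaps)")
```

prints

```
IOIs scored:        262
fluctuation RMSE:   0.0409  (log2 units)
narration matching: 90.1 %
collapse:           3.82 %  (10 gaps)
```

The simulated duet carried multiplicative timing jitter of σ = 0.04 log2
units — recovered by the fluctuation RMSE (0.0409).  5% of notes were sung
with a wrong duration class and 1% of onsets were skipped, so roughly 90% of
IOIs still match the score (narration).  Six multi-second gaps were injected;
the 2-SD gap rule flags those plus a few extreme slow outliers of the LONG
class, giving 10 collapse records (3.8% of IOIs) — the rule is deliberately a
statistical outlier test, not a lookup of injected events.

The same pipeline runs from the shell:

```bash
dyadtiming simulate --config cfg.yaml --seed 3 --out sim
dyadtiming track    --config cfg.yaml --seed 3 --data sim --out run
dyadtiming movement --config cfg.yaml --seed 3 --data sim --out run
dyadtiming report   --config cfg.yaml --seed 3 --data run --out rep
```

`rep/correlations.csv` then holds the Kendall tau-b of every marker against
mean quality and agency, per condition subset; `rep/exclusions.csv` lists
protocol-violating trials with reasons.  Reruns under one seed are
byte-identical.

Real data enter through the same formats: one onset CSV per singer per trial
(`time_s[,label]`), 1000-sample annotation CSVs (integers 0–127), a
`trials.csv` with duo/trial/condition/expert-group/agency columns, and
4-column force-plate CSVs with the sample rate given in the config.

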