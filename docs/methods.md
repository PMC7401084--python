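# Methods

## Signal model

A confocal line-scan acquisition is modelled as a uniformly sampled
fluorescence trace

```
F(tᵢ) = F₀·exp(−tᵢ/τ_bleach) + Σₖ Aₖ·K(tᵢ − tₖ) + εᵢ,   εᵢ ~ N(0, σ²) i.i.d.
```

with `tᵢ = i·Δt` (line period Δt, default 0.075 s). The transient kernel is
the standard minimal Ca²⁺ transient shape, a difference of exponentials

```
K(s) ∝ exp(−s/τ_decay) − exp(−s/τ_rise),   s ≥ 0,
```

normalized so that its *sampled* maximum is exactly 1; event peaks are
snapped to the sampling grid, so in the absence of noise the sampled peak
equals the nominal amplitude exactly. Transient amplitudes are not
attenuated by the bleaching factor — bleaching acts on the resting baseline
only — so the ΔF/F₀ amplitude of a fixed-amplitude train grows slowly
through a scan (by ~65% over 300 s at the default τ_bleach = 600 s). Event
times are jittered uniformly by ±10% of the mean beat interval, so
detection cannot exploit strict periodicity.

A kymograph adds a pixel dimension: each scan line holds the noise-free
trace value plus independent per-pixel Gaussian noise, so the row-mean
recovers the trace with error σ/√n_pixels.

### Default simulation parameters

| parameter | default | rationale |
|---|---|---|
| `line_period_s` | 0.075 s | the reference acquisition protocol (4000 lines = 300 s) |
| `beat_rate_hz` | 0.4 | spontaneous hiPSC-CM beating; leaves a clear inter-beat valley |
| `rise_tau_s` / `decay_tau_s` | 0.15 / 0.3 s | time-to-peak of a few hundred ms, typical of immature CMs, resolvable at 75 ms sampling |
| `amplitude`, `f0` | 100, 100 | ΔF/F₀ ≈ 1 per beat, a realistic reporter response |
| `bleach_tau_s` | 600 s | mild monoexponential photobleaching over a 5-min scan (may be ∞) |
| `noise_sd` | 2 | per-sample amplitude/noise = 50; recovery studies use 10 (SNR 10) |
| `small_amplitude_ratio` | 0.5 | injected events sit at 50% of the nominal amplitude, abnormal by construction (< 0.75) |

### Injected abnormalities

*Double peak*: a secondary hump (0.7× the primary amplitude, halved time
constants) is inserted 30% of the beat cycle after the primary peak, and the
inter-peak trough is clamped at 0.40× the amplitude — far above the 0.25
return tolerance — so the event fails the return-to-baseline criterion by
construction. The narrower secondary kernel guarantees the composite
transient still settles before the next beat at worst-case jitter;
with the full-width kernel this cannot be guaranteed, which is why the hump
sits at 30% rather than later in the cycle.

*Small amplitude*: the event amplitude is multiplied by
`small_amplitude_ratio` (constrained < 0.75).

An abnormal event is never followed immediately by another injected
abnormal event, and the first event of a scan is never a small-amplitude
injection (the previous-amplitude rule cannot judge it). These constraints
make the ground-truth labels *exactly* the labels the classification rule
assigns, so noise-free round trips are well defined. A consequence is that
the realized injected fraction sits slightly below the nominal
per-event probability; recovery tests therefore compare against the
realized ground truth.

## Baseline correction

Photobleaching of the resting baseline is monoexponential to first order.
The default `exponential` model fits `F∞ + a·exp(−t/τ)` in two passes:

1. a least-squares fit to the trace's lower envelope — samples at or below
   a rolling 20th-percentile track (10 s window) — which is robust to the
   positive-going transients;
2. a refit to all samples within +2σ̂ of the first-pass curve, where σ̂ is
   estimated from the median absolute first difference. The envelope subset
   is a low-biased noise quantile (≈1% of F₀ at the default noise level);
   the second pass restores both noise tails of the baseline while still
   excluding transient samples.

The `rolling_percentile` model (10 s window, 10th percentile) is the
fallback when the exponential fit fails to converge, and an explicit
alternative for non-exponential drift. F₀ is the fitted, time-varying
baseline itself — not an early-window mean — making ΔF/F₀ robust over
multi-minute bleaching and exactly scale invariant. Residual transient
tails bias the fitted baseline upward by a few tenths of a percent of F₀;
this is visible only as a sub-1% relative error in ΔF/F₀.

## Event detection

All measurements are taken on a Savitzky–Golay-smoothed copy of the
corrected trace (order 2, 0.5 s window; `smooth_s=0` disables smoothing and
reproduces raw sample values exactly, which is the natural setting for
noise-free data). The quadratic fit preserves smooth transient apices while
suppressing per-sample noise by ~√3.

1. Candidate peaks: `scipy.signal.find_peaks` with prominence ≥
   `prominence_frac` (default 0.2) × the robust (1st–99th percentile) range
   of the trace, and separation ≥ `min_interval_s` (default 0.3 s, resolving
   beating to ~3 Hz).
2. Merging: a candidate peak is merged into the running event when the
   trace between the previous peak and the candidate never holds at or
   below `pre_baseline + 0.25·amplitude` for 2 consecutive samples. A
   merged event *is* a double peak: one transient that rises again before
   reaching baseline.
3. Onset and pre-event baseline: the onset is the last near-minimum sample
   of the preceding valley (within half a prominence of the valley floor),
   and the pre-event baseline is the median of the raw corrected trace over
   0.75 s ending at the onset. Anchoring at the *last* near-minimum keeps
   the window on the valley floor rather than the previous decay tail.
4. Amplitude: the mean of the three smoothed samples bracketing the apex,
   minus the pre-event baseline (the raw apex sample when smoothing is
   disabled). Events whose amplitude falls below the prominence threshold
   are discarded — slope-riding noise bumps can carry inflated prominences
   — as are events within one smoothing window of either trace edge.
5. Return to baseline: an event returns iff the smoothed trace holds at or
   below `pre_baseline + return_tolerance_frac·amplitude` (default 0.25)
   for 2 consecutive samples between its last peak and the next event.
   Requiring a sustained dip rather than a single sample makes the flag
   robust to noise at SNR 10.

## Classification and summaries

Event *i* is labelled `abnormal_double_peak` if it did not return to
baseline; otherwise `abnormal_small_amplitude` if
`amplitude_i < 0.75·amplitude_{i−1}`; otherwise `normal`. Double peak takes
precedence (one event, one label; the return failure is the more specific
defect) and the first event has no predecessor, so only the double-peak
criterion can flag it. The label of an event depends only on its own return
flag and its immediate predecessor's amplitude — permuting later events can
never change an earlier label.

Scans are the replication unit: `pct_abnormal` is computed per scan
(`summary_mode: per_scan`), with an event-pooled mode behind a flag. An
empty scan reports a missing percentage, not 0. Beat rate is
`60·n_events/duration_s`.

## Expression and qPCR quantification

`percent_positive` gates per-cell intensities at a fixed threshold or an
automatic one: the midpoint of the two k-means centers on log₁₀ intensity.
The automatic cut refuses apparently unimodal data (center separation
< 4× the pooled within-cluster spread; a single Gaussian split at its mean
yields ≈2.65×). `ddct` follows the classic Livak convention: arithmetic
mean of Ct per (sample, gene), ΔCt = target − housekeeping, ΔΔCt referenced
to a calibrator, fold = 2^(−ΔΔCt), amplification efficiency fixed at 2 (no
Pfaffl correction); replicate SD is propagated as √(SD²_t/n_t + SD²_h/n_h).
`group_compare` delegates to scipy/statsmodels (one-way ANOVA with Tukey,
Dunnett or Šidák post-hoc; unpaired t-test; Kruskal–Wallis), except Dunn's
rank-based post-hoc test, which is implemented here (normal approximation
on mean ranks with tie correction, Bonferroni-adjusted) since no installed
package provides it. Stars follow the usual thresholds
(\*<0.05, \*\*<0.01, \*\*\*<0.001, \*\*\*\*<0.0001).

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis relies on —
transient trains with jitter, monoexponential bleaching, additive Gaussian
noise, and the two abnormality classes in unambiguous form. It does not
model biophysical Ca²⁺ fluxes, PMT/shot-noise physics, motion artifacts,
cell-to-cell kinetic variability, or sub-sample peak alignment (event peaks
sit on the sampling grid). Passing the recovery tests therefore shows the
pipeline is correct and unbiased under these assumptions, not that it
reproduces any particular laboratory measurement; pClamp's proprietary
event detection is not claimed to be matched event-for-event.

## Numerical choices and problem sizes

Tests and the acceptance script use 300 s scans at the 75 ms line period
(4000 samples, ~118 events at 0.4 Hz); recovery studies use 50 scans per
condition at amplitude/noise 10, the hardest signal-to-noise the recovery
properties are stated for, and check pooled recovered abnormal fractions
against the 95% binomial interval of the realized injected fraction. The
no-injection false-positive rate measures at ~0.1–0.3% of events against a
1% budget; its dominant term is amplitude-ratio measurement noise at the
0.75 threshold. Determinism is exact: all randomness flows through
`numpy.random.SeedSequence` from one integer seed, and rerunning a
configuration byte-identically reproduces the summary JSON.

## Known limitations

- The abnormality rule is threshold-based; events with true ratios near
  0.75 are intrinsically ambiguous at finite SNR.
- The exponential baseline assumes monotone single-component bleaching; use
  the rolling-percentile model for other drift shapes.
- Amplitudes are measured on the smoothed trace; with smoothing enabled
  they carry a small, kinetics-dependent but event-consistent attenuation
  (ratios, and hence classification, are unaffected).
- Very small injected amplitude ratios can drop events below the detection
  threshold entirely; the "more abnormal ⇒ no fewer detections" property
  holds only above it.
- `percent_positive`'s automatic threshold assumes a two-component,
  well-separated intensity mixture on the log scale.
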