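# Methods

This note documents the models and procedures photoperant implements, the
tunable parameters and their defaults, what the synthetic-data generator does
and does not emulate, and the numerical and design choices made where the
procedure admitted more than one reading.

## Photometry preprocessing

The signal model is bulk axonal GCaMP6s fluorescence sampled at a fixed rate
(default 20 Hz) with slow multiplicative decay from photobleaching. No
isosbestic reference channel is used: GCaMP6s has an excitation peak in the
405–410 nm band, so a calcium-independent reference is not available for
this indicator, and motion/hemodynamic correction is out of scope.

1. **Detrending.** F̂(t) = A₁e^(−t/τ₁) + A₂e^(−t/τ₂) is fitted to the raw
   trace by bounded least squares with a soft-L1 (robust) loss,
   `f_scale` = 0.1% of the median intensity, so that event-locked transients
   — which sit only above the bleach envelope and would otherwise drag the
   fit upward — have little leverage. Multi-start initialization tries τ
   pairs (30, 300) s, (120, 1500) s, and (T/20, T); amplitudes are split
   from the head/tail means of the trace; all parameters are bounded
   positive. If no start converges, a single exponential is fitted instead
   and a warning issued. An all-constant trace short-circuits to the
   degenerate fit F̂ ≡ mean(F). The trace is *divided* by the fit
   (normalized = F/F̂): division yields a unitless, trend-free signal whose
   transient amplitudes are fractions of local baseline, which is what ΔF/F₀
   operates on; subtraction would leave amplitudes tied to absolute
   intensity. No constant offset term is included in the fit — any floor is
   absorbed by the running-percentile baseline in the next step.

2. **Running baseline.** F₀(t) is the 10th percentile of the normalized
   trace in a 15 s window centered on each sample and truncated (not padded)
   at the session edges. Percentiles use linear interpolation between order
   statistics. Centering is a choice — a trailing window would lag transients
   more but react identically to slow drift; the alignment is configurable.

3. **ΔF/F₀** = (normalized − F₀)/F₀, defined only for F₀ > 0 (guaranteed on
   real positive traces).

4. **Session QC.** A session is kept only if the 97.5th percentile of its
   ΔF/F₀, over the whole trace and independent of behavior, exceeds 0.01
   (a 1% change) — i.e. the recording exhibits transients at all.

Tunables: `baseline_window_s` (15 s), `baseline_percentile` (10),
`qc_percentile` (97.5), `qc_threshold` (0.01).

## Peri-event analysis

Trials span −5 to +5 s around an event in 50 ms bins (200 bins); each bin is
the mean of its ΔF/F₀ samples. Trials whose window would cross a session
edge are dropped and counted, never padded. Each session × event-type trial
set is z-scored against the *pooled* mean and sample SD (ddof = 1) of all
its baseline-window bins (−5 to −2 s): the pooled convention reads the
baseline as a session property; a per-trial variant exists behind
`per_trial_zscore` for sensitivity analysis only. Zero pooled variance flags
the session and excludes its trials.

**Outlier removal** operates on the trial "peak amplitude": the signed
extremum (maximum |z|, sign preserved) within the analysis window
(−2 to 2 s). Fences are median ± 3 × (1.4826 × MAD) of the peak distribution
— the 1.4826 constant makes the MAD a consistent SD estimate under
normality, so the fence approximates ±3σ while being immune to the outliers
it hunts. Fences are computed once per group × event type from the full
trial set (single pass; order-independent). A zero MAD (pathological:
majority of identical peaks) keeps only trials at the median and warns.

**Net AUC** is the signed area of z over the analysis window, computed as
the midpoint sum (bin value × 50 ms). For the 80-bin window this makes a
constant z = 1 integrate to exactly 4.0 z·s and agrees with smooth traces to
O(bin²) (the half-sine test case is recovered to < 1e−3). Negative
excursions subtract.

**Aggregation.** "All event trials" keeps every trial row, preserving
within-subject variance; "session average" collapses to one mean row per
session, exposing only between-subject variability. With unequal trial
counts the two grand means differ by construction (unweighted session means
vs pooled trials); both are reported.

## Group inference

**Permutation test.** Per analysis-window bin, the statistic is the
difference of group mean z. Trials (rows) are the exchange unit — bins are
never permuted independently. The pooled trials are randomly re-partitioned
`n_permutations` = 1000 times preserving group sizes;
p = (1 + #{|null| ≥ |observed|}) / (n_perm + 1) (add-one smoothing, so p is
never 0 and min p = 1/1001). The null SD per bin is retained in the result
for a z-approximation cross-check. Benjamini–Hochberg FDR correction is
applied across the 80 analysis-window bins only, per comparison. Significant
epochs are maximal runs of ≥ `min_run` = 4 consecutive bins with adjusted
p < 0.05, reported as time intervals; the run-length gate suppresses
isolated bins that survive correction by chance.

Calibration properties verified by the test suite: under the null (both
groups from the same generator, 30 trials each) the raw per-bin
false-positive rate is 5% ± 1% and fewer than 5% of replicates report any
epoch after FDR + gating; a planted +2 z offset confined to 0–1 s is
detected, and confined to its window, in ≥ 95 of 100 replicates.

**KS test** (`scipy.stats.ks_2samp`, asymptotic p) compares bout-metric
distributions between groups. **Devaluation index**: per subject, valued
proportion = valued/(valued + devalued) presses across the two test days;
sensitivity to devaluation is a one-sample t of the proportions against 0.5.
Subjects with zero total presses are excluded with a log entry; zero
variance across subjects (all proportions identical) flags the t as
undefined rather than raising.

## Bout segmentation

The split threshold is the mean of *all* inter-press intervals in the
session, long between-bout pauses included (the threshold must be computable
before bouts exist). The press sequence is cut at every IPI strictly greater
than the mean — equality keeps presses together — and clusters of ≥ 3
presses are retained as bouts. Duplicate press timestamps (hardware edge
artifacts) are collapsed with a warning, since a zero IPI would corrupt the
threshold. The threshold is recomputed per session, never pooled. With
perfectly regular pressing no IPI exceeds the mean and the session is one
bout — the degenerate case is intentional, not an error.

## Rotation counting

Frame-to-frame differences of the (unwrapped) orientation are summed in a
single running accumulator; reaching +6.28 rad counts a clockwise rotation
and resets the accumulator to 0, and −6.28 a counter-clockwise one. Two
readings deserve note:

* The threshold is literally 6.28 rad, not 2π — the 0.0032 rad difference
  decides exact-full-turn edge cases. It is configurable
  (`rotation_threshold_rad`).
* Reset-to-zero discards any overshoot past the threshold, so a continuous
  ramp of exactly 4π can count 1 or 2 turns depending on how the frames
  discretize it. Jitter-free generated trajectories (turns of exactly 2π,
  frame increments dividing the turn evenly) are counted exactly; real or
  jittered trajectories sit 0.0032 rad from the knife edge on every
  exact-2π turn, which is a property of the literal threshold, not of this
  implementation.
* The shared accumulator means progress toward one direction is eroded by
  movement in the other. An `independent` two-accumulator variant (one per
  direction, each floored at zero from the opposite side) is available via
  `rotation_mode`.

Wrapped tracker output is unwrapped before differencing (any jump > π
between frames is interpreted as a wrap).

## Ephys plasticity metrics

Slow protocol (0.05 Hz evoked EPSCs, 40 min): amplitudes are normalized to
the 10 min baseline mean (= 100%), combined in 2 min bins anchored at the
recording start (empty bins are reported missing, partial bins with their
count), and the LTD magnitude is the mean normalized amplitude for
30 ≤ t ≤ 40 min. Fast protocol (0.2 Hz, per-trial): 30 s baseline, 10 s
depolarization, 120 s recovery; per trial the DSE magnitude is
100 − normalized% at the first evoked response after depolarization (a
single sweep, not a bin average), averaged over the three trials of a
neuron; larger values mean more suppression. Both metrics are invariant to
the absolute baseline amplitude. Spike counting for F–I curves uses upward
crossings of 0 mV with a 2 ms refractory lockout (the counting criterion is
not standardized; threshold and lockout are configurable).

## Synthetic data

The generator produces inputs with the statistical structure the analysis
assumes; it makes no attempt at biophysics (no calcium dynamics, no
spike-to-fluorescence model, no mechanistic account of how chronic ethanol
changes circuits).

* **Behavior**: bouts of presses with truncated-normal within-bout IPIs
  (lower bound 0.2 s). The location parameter is solved numerically so the
  *truncated* mean equals the configured group mean — 1.84 s for the
  air-control preset, 1.31 s for the chronic-ethanol preset — otherwise the
  truncation bias (~0.04 s) would shift every downstream recovery check.
  Bout sizes are Poisson (mean 8), between-bout gaps shifted-exponential
  (min 10 s, mean 60 s). Reinforcement is per-press Bernoulli with
  p = 1/ratio (the standard operationalization of a random-ratio schedule);
  sessions end at 30 reinforcers or 3600 s, whichever first. Every outcome
  is followed by a retrieval head entry at a log-normal latency; spontaneous
  entries arrive at a configurable Poisson rate so non-rewarded entries
  exist. The configured IPI SDs (0.50/0.35 s) are lighter-tailed than real
  IPI distributions (whose SEMs imply an SD near 1.9 s and heavy skew);
  heavy tails would make planted bouts non-recoverable by the mean-IPI rule
  and are deliberately not modeled — so segmentation-recovery tests validate
  the algorithm, not its behavior on extreme real-world IPI distributions,
  and between-group KS distances run larger than in real data.
* **Photometry**: trace = bleach(t) × (1 + Σ responses + noise). The bleach
  envelope is the double exponential plus a constant floor, sized so the
  default session loses ~28% intensity over an hour (a floor is required:
  with time constants of 120 and 1500 s alone, less than 10% of the slow
  component survives an hour). The transient kernel is a peak-normalized
  difference of exponentials (rise 0.2 s, decay 1.5 s), the conventional
  GCaMP6s-like shape; responses add linearly with per-event-type fractional
  amplitudes. Optional spontaneous transients (Poisson rate, log-normal
  amplitudes; 0.1 Hz in the group presets, off by default) emulate ongoing
  background activity. Even with them, the synthetic baseline is less
  variable than real population recordings, so peri-event z-scores and AUCs
  run larger than physiological values; tests therefore check recovery of
  *planted* amplitudes and group *contrasts*, never absolute z magnitudes.
* **Orientation**: planted full turns of exactly ±2π as linear ramps in
  randomized order with stationary pauses; optional per-frame angular jitter
  and wrapping. With zero jitter the net displacement is exactly
  2π(n_cw − n_ccw).
* **EPSC series**: step depression to a configured fraction of baseline at
  onset (slow protocol), or a per-trial dip recovering exponentially with a
  20 s time constant (fast protocol; the first post-depolarization sweep
  carries the planted dip). Gaussian amplitude noise optional. Group presets
  carry typical published magnitudes for the two protocols (e.g. a step to
  54.6% of baseline; first-point suppression near 26% and 42%) so
  group-contrast code paths are exercised at realistic effect sizes.

All generators are deterministic under a fixed seed.

## Problem sizes and numerical notes

The statistical calibration suites use 200 null replicates and 100 power
replicates at 30 trials per group, 10 detrending recovery curves at 20 Hz ×
30 min, 1000 random press sequences for the segmentation oracle, and 100
planted trajectories for rotation counting; the end-to-end demonstration in
`scripts/acceptance.py` simulates 200 behavioral sessions per group and 6
photometry sessions of 11 min per group. These sizes were chosen to give
stable Monte-Carlo estimates while keeping a full run in tens of seconds.

Numerical conventions: percentile = linear interpolation between order
statistics; baseline SD uses ddof = 1; permutation p uses add-one smoothing;
the AUC midpoint rule is exact for constants; fence comparisons are ≤ (a
trial exactly on the fence is kept); CSV readers parse floats in round-trip
mode so writer/reader pairs are lossless.

## Known limitations

* No isosbestic or motion correction; the detrend + running-percentile chain
  assumes artifacts are slow relative to 15 s.
* The permutation unit for session-average comparisons is the row of the
  aggregated matrix (sessions), not mice; with multiple sessions per animal
  this understates between-animal dependence.
* The generator's IPI and baseline-variability distributions are
  lighter-tailed than real data (see above); passing recovery tests show
  algorithmic correctness at the configured conditions, not robustness to
  every empirical distribution.
* DSE "first point" is read as a single sweep; if an acquisition averages
  the first bin instead, magnitudes will differ slightly.
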