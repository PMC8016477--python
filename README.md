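# photoperant

Analysis pipeline for fiber-photometry recordings of cortico-striatal axon
terminals during self-paced operant behavior, with companion tools for the
behavioral, rotational, and slice-electrophysiology assays that typically
accompany such experiments — and a synthetic-data generator that emulates the
statistical structure of every input, so the whole stack is testable end to
end without any recording on disk.

It is written for behavioral-neuroscience labs that align bulk calcium
signals (e.g. axonal GCaMP6s measured in dorsal striatum) to lever presses,
head entries, and reward deliveries, and need the full chain from raw
fluorescence to group-level inference to be reproducible and unit-tested.

## What the pipeline computes

**Photometry preprocessing.** A raw fluorescence trace F(t) is detrended by a
robust least-squares fit of a double exponential

    F̂(t) = A₁·e^(−t/τ₁) + A₂·e^(−t/τ₂)

(photobleaching + signal decay), normalized to the fit, and referenced to a
running baseline F₀ — the 10th percentile of the normalized trace in a
centered 15 s window — giving ΔF/F₀ = (F/F̂ − F₀)/F₀. Sessions pass QC only
if the 97.5th percentile of ΔF/F₀ exceeds a 1% change.

**Peri-event tensors.** "Trials" are ΔF/F₀ from −5 to +5 s around each
behavioral event in 50 ms bins (200 bins), z-scored to the pooled mean and SD
of the session's pre-event baseline (−5 to −2 s). Outlier trials — peak |z|
beyond median ± 3 scaled MADs (MAD × 1.4826) of the group's trial peaks — are
removed. The net AUC is the signed area of z over the analysis window
(−2 to 2 s), in z·s. Two aggregation modes are supported: every trial row
("all event trials", preserving within-subject variance) or one mean row per
session ("session average").

**Group statistics.** Per 50 ms bin, a two-group permutation test: trials are
pooled and re-partitioned 1000 times preserving group sizes; the two-sided p
is the add-one-smoothed rank of the observed group-mean difference in the
null. Benjamini–Hochberg FDR correction is applied across the 80
analysis-window bins, and only runs of ≥ 4 consecutive significant bins count
as significant epochs. Also: two-sample Kolmogorov–Smirnov comparisons of
bout metrics, and the outcome-devaluation index (per-subject valued-press
proportion tested against 0.5).

**Behavior.** Lever-press bouts are clusters separated by inter-press
intervals greater than the session-mean IPI; only clusters of ≥ 3 presses are
kept. Head entries are classified as outcome-retrieval (first entry after an
outcome) or non-rewarded.

**Rotation assay.** A running accumulator of frame-to-frame orientation
differences counts a clockwise turn at +6.28 rad and a counter-clockwise turn
at −6.28 rad, resetting to zero at each count.

**Slice ephys.** Evoked-EPSC series are normalized to their baseline epoch;
LTD magnitude is the mean normalized amplitude 30–40 min after induction, and
DSE magnitude is the suppression (100 − normalized %) at the first evoked
response after depolarization, averaged over trials. Spike counts for F–I
curves use threshold crossings with a 2 ms lockout.

## Worked example

Simulate one session, preprocess it, and segment its lever-press bouts:

```bash
photoperant simulate --kind photometry --seed 7 --out session/
photoperant preprocess session/trace.csv --out session/
photoperant bouts session/events.csv --out session/
```

The `bouts` step prints:

```json
{
  "n_bouts": 45,
  "presses_per_bout_mean": 7.511111111111111,
  "within_bout_ipi_mean_s": 1.8760307008237522,
  "bout_duration_mean_s": 12.215044340919098
}
```

i.e. the presses of this simulated hour-long session fall into 45 bouts of
~7.5 presses each, with a mean within-bout inter-press interval of ~1.88 s
(the simulated control-group condition is 1.84 s) and mean bout duration
~12.2 s. The `preprocess` step reports the session QC verdict:
`"qc_passed": true, "qc_value": 0.0438` — the 97.5th percentile of ΔF/F₀ is
a 4.4% change, well above the 1% inclusion threshold.

The same stages are available as library calls (`photoperant.photometry`,
`.perievent`, `.group_stats`, `.behavior`, `.rotation`, `.ephys`,
`.synthetic`), and `photoperant run manifest.csv --out results/` executes the
whole chain — preprocess → QC → peri-event tensors → outlier removal →
permutation comparison — over a manifest of sessions, writing tidy CSV
tables (group traces ± SEM, p-values, significant epochs, AUC records, bout
metrics, QC log, exclusion log).

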