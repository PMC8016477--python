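"""Synaptic plasticity metrics from evoked-EPSC amplitude series.

Two protocols are quantified:

* slow (0.05 Hz) recordings for long-term depression (LTD): amplitudes are
  normalized to the 10 min baseline mean (=100%), combined in 2 min bins, and
  the LTD magnitude is the mean normalized amplitude between 30 and 40 min;
* fast (0.2 Hz) depolarization-induced suppression of excitation (DSE)
  trials: per trial, amplitudes are normalized to the 30 s baseline, and the
  DSE magnitude is the suppression (100 - normalized %) at the first evoked
  response after the depolarization, averaged over the three trials of a
  neuron.  Larger DSE magnitude = more suppression.

Also provides spike counting for current-step (F-I) protocols.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np

from .datatypes import EPSCSeries


class EphysError(ValueError):
    pass


def normalize_to_baseline(
    series: EPSCSeries, baseline_window: tuple[float, float] | None = None
) -> EPSCSeries:
    """Express amplitudes as percent of the baseline-window mean (per trial).

    The default baseline window is (0, baseline_end) from the series'
    epoch marks, or (0, 10) min / (0, 30) s by protocol convention.
    """
    if baseline_window is None:
        end = series.epoch_marks.get(
            "baseline_end", 10.0 if series.time_unit == "min" else 30.0
        )
        baseline_window = (series.time.min() if series.time.size else 0.0, end)

    out_amp = np.empty_like(series.amplitude_pA)
    for tid, t, amp in series.trials():
        m = series.trial_id == tid
        bmask = (t >= baseline_window[0]) & (t < baseline_window[1])
        if bmask.sum() < 3:
            raise EphysError(f"trial {tid}: need at least 3 baseline points")
        base = amp[bmask].mean()
        if base <= 0:
            raise EphysError(f"trial {tid}: zero baseline mean")
        out_amp[m] = 100.0 * amp / base
    return replace(series, amplitude_pA=out_amp)


def bin_series(
    time_min: np.ndarray, normalized: np.ndarray, bin_min: float = 2.0
):
    """Mean of normalized values per contiguous bin anchored at time 0.

    Returns ``(bin_start_min, bin_mean, bin_count)``; empty bins are NaN with
    count 0, never silently zero.  Partial final bins are reported with their
    count.
    """
    if bin_min <= 0:
        raise EphysError("bin width must be > 0")
    t = np.asarray(time_min, dtype=float)
    x = np.asarray(normalized, dtype=float)
    n_bins = int(np.floor(t.max() / bin_min)) + 1 if t.size else 0
    idx = np.floor(t / bin_min).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=x, minlength=n_bins)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return np.arange(n_bins) * bin_min, means, counts


def ltd_magnitude(
    time_min: np.ndarray,
    normalized: np.ndarray,
    window_min: tuple[float, float] = (30.0, 40.0),
) -> float:
    """Mean normalized amplitude (percent of baseline) in the 30-40 min window."""
    t = np.asarray(time_min, dtype=float)
    x = np.asarray(normalized, dtype=float)
    if t.size == 0 or t.max() < window_min[1] - 1e-9:
        raise EphysError(f"series must extend to {window_min[1]} min")
    m = (t >= window_min[0]) & (t <= window_min[1])
    return float(x[m].mean())


def dse_magnitude(series: EPSCSeries) -> tuple[float, np.ndarray]:
    """Suppression at the first evoked response after depolarization.

    ``series`` holds one or more trials on a within-trial time axis (s), with
    ``depolarization_end`` (and optionally ``baseline_end``) epoch marks.  Per
    trial: normalize to the baseline, take the first point at or after
    depolarization end, suppression = 100 - normalized%.  Returns the
    across-trial mean and the per-trial values.  Invariant to the absolute
    baseline amplitude of each trial.
    """
    if "depolarization_end" not in series.epoch_marks:
        raise EphysError("missing 'depolarization_end' epoch mark")
    depol_end = series.epoch_marks["depolarization_end"]
    base_end = series.epoch_marks.get(
        "baseline_end", series.epoch_marks.get("depolarization_start", depol_end)
    )
    norm = normalize_to_baseline(series, baseline_window=(0.0, base_end))
    per_trial = []
    for tid, t, amp in norm.trials():
        post = np.flatnonzero(t >= depol_end - 1e-9)
        if post.size == 0:
            raise EphysError(f"trial {tid}: no point after depolarization")
        per_trial.append(100.0 - amp[post[0]])
    per_trial = np.array(per_trial)
    return float(per_trial.mean()), per_trial


def count_spikes(
    voltage_mV: np.ndarray,
    sampling_rate_hz: float,
    threshold_mV: float = 0.0,
    refractory_s: float = 0.002,
) -> int:
    """Number of upward threshold crossings with a refractory lockout.

    A crossing within ``refractory_s`` of the previous counted one is treated
    as the same spike (guards doublets from noisy waveforms).
    """
    v = np.asarray(voltage_mV, dtype=float)
    if not np.all(np.isfinite(v)):
        raise EphysError("voltage trace must be finite")
    if v.size < 2:
        return 0
    up = np.flatnonzero((v[:-1] < threshold_mV) & (v[1:] >= threshold_mV)) + 1
    lockout = refractory_s * sampling_rate_hz
    count = 0
    last = -np.inf
    for i in up:
        if i - last >= lockout:
            count += 1
            last = i
    return count
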