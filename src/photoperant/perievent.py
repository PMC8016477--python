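"""Peri-event trial tensors: extraction, z-scoring, outlier removal, net AUC.

A "trial" is the dF/F0 signal from -5 to +5 s around one behavioral event,
averaged into 50 ms bins (200 bins).  Trials are z-scored against the pooled
mean and SD of the pre-event baseline window (-5 to -2 s) across all trials
of that session and event type, so a z of +2 means two baseline SDs above the
session's typical pre-event signal.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .config import PipelineConfig
from .photometry import DffTrace


class PeriEventError(ValueError):
    pass


def bin_centers(window: tuple[float, float] = (-5.0, 5.0), bin_s: float = 0.05) -> np.ndarray:
    n = int(round((window[1] - window[0]) / bin_s))
    return window[0] + (np.arange(n) + 0.5) * bin_s


@dataclass
class PeriEventTensor:
    """trials x bins matrix of z-scored dF/F0 around one event type."""

    z: np.ndarray                      # (n_trials, n_bins)
    bin_centers_s: np.ndarray
    event_type: str = ""
    session_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    event_times_s: np.ndarray = field(default_factory=lambda: np.array([]))
    baseline_window_s: tuple[float, float] = (-5.0, -2.0)
    analysis_window_s: tuple[float, float] = (-2.0, 2.0)

    def __post_init__(self) -> None:
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        if self.session_ids.size == 0 and self.z.shape[0]:
            self.session_ids = np.array([""] * self.z.shape[0], dtype=object)
        if self.event_times_s.size == 0 and self.z.shape[0]:
            self.event_times_s = np.full(self.z.shape[0], np.nan)

    @property
    def n_trials(self) -> int:
        return self.z.shape[0]

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        c = self.bin_centers_s
        return (c >= window[0]) & (c < window[1])


def extract_trials(
    dff: DffTrace,
    event_times: np.ndarray,
    window: tuple[float, float] = (-5.0, 5.0),
    bin_s: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Cut raw (not yet z-scored) peri-event trials out of a dF/F0 trace.

    Each trial bin holds the mean of the dF/F0 samples falling in that 50 ms
    bin.  Events whose window would cross a session edge are dropped (and
    counted), never padded.

    Returns ``(raw_matrix, kept_event_times, n_dropped)``; with no valid
    events the matrix is empty (0 x n_bins), which is flagged by the caller,
    not an error.
    """
    event_times = np.asarray(event_times, dtype=float)
    n_bins = int(round((window[1] - window[0]) / bin_s))
    t0, t1 = dff.time_s[0], dff.time_s[-1]
    fs = dff.sampling_rate_hz

    keep = (event_times + window[0] >= t0 - 1e-9) & (event_times + window[1] <= t1 + 1e-9)
    kept = event_times[keep]
    n_dropped = int(event_times.size - kept.size)

    rows = np.empty((kept.size, n_bins))
    # sample i is at time t0 + i/fs; assign samples to bins by index arithmetic
    for r, te in enumerate(kept):
        rel_start = te + window[0] - t0
        i0 = int(np.ceil(rel_start * fs - 1e-9))
        i1 = int(np.floor((te + window[1] - t0) * fs + 1e-9))
        idx = np.arange(i0, min(i1 + 1, dff.dff.size))
        b = np.floor(((idx / fs) - rel_start) / bin_s + 1e-9).astype(int)
        ok = (b >= 0) & (b < n_bins)
        idx, b = idx[ok], b[ok]
        sums = np.bincount(b, weights=dff.dff[idx], minlength=n_bins)
        counts = np.bincount(b, minlength=n_bins)
        if np.any(counts == 0):
            raise PeriEventError("empty peri-event bin: bin width below sampling interval")
        rows[r] = sums / counts
    return rows, kept, n_dropped


def zscore_trials(
    raw: np.ndarray,
    centers: np.ndarray,
    baseline_window: tuple[float, float] = (-5.0, -2.0),
    analysis_window: tuple[float, float] = (-2.0, 2.0),
    event_type: str = "",
    session_id: str = "",
    event_times: np.ndarray | None = None,
    per_trial: bool = False,
) -> PeriEventTensor:
    """Z-score one session's raw trial matrix against its pooled pre-event
    baseline (all baseline-window bins of all trials, sample SD).

    ``per_trial=True`` switches to per-trial baselines (sensitivity analysis
    only; the default pooled convention is the primary one).
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    centers = np.asarray(centers, dtype=float)
    bmask = (centers >= baseline_window[0]) & (centers < baseline_window[1])
    if bmask.sum() < 2:
        raise PeriEventError("need at least 2 baseline bins")
    if raw.shape[0] == 0:
        z = raw
    elif per_trial:
        mu = raw[:, bmask].mean(axis=1, keepdims=True)
        sd = raw[:, bmask].std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise PeriEventError("zero baseline variance in at least one trial")
        z = (raw - mu) / sd
    else:
        base = raw[:, bmask].ravel()
        mu, sd = base.mean(), base.std(ddof=1)
        if sd == 0:
            raise PeriEventError(f"zero pooled baseline variance in session {session_id!r}")
        z = (raw - mu) / sd

    n = raw.shape[0]
    return PeriEventTensor(
        z=z,
        bin_centers_s=centers,
        event_type=event_type,
        session_ids=np.array([session_id] * n, dtype=object),
        event_times_s=(np.asarray(event_times, dtype=float)
                       if event_times is not None else np.full(n, np.nan)),
        baseline_window_s=baseline_window,
        analysis_window_s=analysis_window,
    )


def concat_tensors(tensors: list[PeriEventTensor]) -> PeriEventTensor:
    tensors = [t for t in tensors if t.n_trials > 0]
    if not tensors:
        raise PeriEventError("no trials to concatenate")
    first = tensors[0]
    return PeriEventTensor(
        z=np.vstack([t.z for t in tensors]),
        bin_centers_s=first.bin_centers_s,
        event_type=first.event_type,
        session_ids=np.concatenate([t.session_ids for t in tensors]),
        event_times_s=np.concatenate([t.event_times_s for t in tensors]),
        baseline_window_s=first.baseline_window_s,
        analysis_window_s=first.analysis_window_s,
    )


def trial_peaks(tensor: PeriEventTensor) -> np.ndarray:
    """Signed extremum (max by |z|, sign kept) per trial in the analysis window."""
    mask = tensor.window_mask(tensor.analysis_window_s)
    zw = tensor.z[:, mask]
    idx = np.argmax(np.abs(zw), axis=1)
    return zw[np.arange(zw.shape[0]), idx]


def remove_outlier_trials(
    tensor: PeriEventTensor, k: float = 3.0, mad_scale: float = 1.4826
) -> tuple[PeriEventTensor, np.ndarray]:
    """Drop trials whose peak z lies outside median +/- k * scaled MAD.

    The scaled MAD (MAD * 1.4826) is a robust, normal-consistent SD estimate,
    so k=3 approximates a 3-sigma two-sided fence.  Fences are computed once
    from the full trial set (single pass, order independent).  Returns the
    filtered tensor and the boolean keep-mask.
    """
    if tensor.n_trials < 3:
        raise PeriEventError("need at least 3 trials for outlier fences")
    peaks = trial_peaks(tensor)
    med = np.median(peaks)
    mad = np.median(np.abs(peaks - med))
    if mad == 0:
        warnings.warn("zero MAD of trial peaks; keeping only trials at the median")
        keep = peaks == med
    else:
        keep = np.abs(peaks - med) <= k * mad_scale * mad
    out = replace(
        tensor,
        z=tensor.z[keep],
        session_ids=tensor.session_ids[keep],
        event_times_s=tensor.event_times_s[keep],
    )
    return out, keep


def net_auc(
    z: np.ndarray,
    centers: np.ndarray,
    window: tuple[float, float] = (-2.0, 2.0),
    bin_s: float | None = None,
) -> np.ndarray | float:
    """Signed area under z over the window, in z * seconds.

    Computed as the midpoint (rectangle) sum of bin values times the bin
    width; excursions below zero subtract.  Accepts a single trace or a
    trials x bins matrix (one AUC per row).
    """
    z = np.asarray(z, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if bin_s is None:
        bin_s = float(np.median(np.diff(centers)))
    mask = (centers >= window[0]) & (centers < window[1])
    if not mask.any():
        raise PeriEventError("AUC window contains no bins")
    if z.ndim == 1:
        return float(np.sum(z[mask]) * bin_s)
    return np.sum(z[:, mask], axis=1) * bin_s


def aggregate(tensor: PeriEventTensor, mode: str = "all_event_trials"):
    """The two aggregation conventions for group traces and AUC records.

    ``all_event_trials`` keeps every trial row (preserves within-subject
    variance); ``session_average`` averages rows per session first (one row
    per session; between-subject variability only).  Returns
    ``(rows, row_ids, auc)`` where ``auc`` has one net AUC per returned row.
    """
    if tensor.n_trials == 0:
        raise PeriEventError("empty tensor")
    if mode == "all_event_trials":
        rows = tensor.z
        ids = tensor.session_ids
    elif mode == "session_average":
        uniq = list(dict.fromkeys(tensor.session_ids))  # stable order
        rows = np.vstack([tensor.z[tensor.session_ids == s].mean(axis=0) for s in uniq])
        ids = np.array(uniq, dtype=object)
    else:
        raise PeriEventError(f"unknown aggregation mode {mode!r}")
    auc = net_auc(rows, tensor.bin_centers_s, window=tensor.analysis_window_s)
    return rows, ids, np.atleast_1d(auc)
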