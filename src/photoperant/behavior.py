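"""Lever-press bout segmentation, bout metrics, and head-entry classification.

Bouts are defined from the session itself: the mean of *all* inter-press
intervals (IPIs) in the session — long between-bout pauses included — is the
split threshold, and the press sequence is cut at every IPI strictly greater
than that mean.  Only clusters of at least three presses count as bouts.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import EventStream


@dataclass
class Bout:
    """A retained cluster of >= 3 presses."""

    press_times_s: np.ndarray
    onset_s: float = field(init=False)
    offset_s: float = field(init=False)
    n_presses: int = field(init=False)
    ipis_s: np.ndarray = field(init=False)
    duration_s: float = field(init=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.press_times_s, dtype=float)
        self.press_times_s = t
        self.onset_s = float(t[0])
        self.offset_s = float(t[-1])
        self.n_presses = int(t.size)
        self.ipis_s = np.diff(t)
        self.duration_s = float(t[-1] - t[0])


@dataclass
class BoutSummary:
    n_bouts: int
    presses_per_bout: np.ndarray
    within_bout_ipis_s: np.ndarray     # pooled across bouts
    durations_s: np.ndarray


def segment_bouts(press_times: np.ndarray, min_presses: int = 3) -> list[Bout]:
    """Split the press sequence at IPIs above the session-mean IPI.

    Equality keeps presses together (the threshold is "strictly greater").
    Duplicate timestamps are collapsed to one press with a warning, since a
    zero IPI would corrupt the mean threshold.  Fewer than 2 presses yields no
    IPIs, hence no bouts.
    """
    t = np.asarray(press_times, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("press times must be sorted")
    dup = t.size - np.unique(t).size
    if dup:
        warnings.warn(f"collapsed {dup} duplicate press timestamp(s)")
        t = np.unique(t)
    if t.size < 2:
        return []
    ipis = np.diff(t)
    threshold = ipis.mean()
    cut_after = np.flatnonzero(ipis > threshold)
    starts = np.concatenate([[0], cut_after + 1])
    ends = np.concatenate([cut_after + 1, [t.size]])
    return [Bout(t[s:e]) for s, e in zip(starts, ends) if e - s >= min_presses]


def bout_metrics(bouts: list[Bout]) -> BoutSummary:
    if not bouts:
        return BoutSummary(0, np.array([], dtype=int), np.array([]), np.array([]))
    return BoutSummary(
        n_bouts=len(bouts),
        presses_per_bout=np.array([b.n_presses for b in bouts]),
        within_bout_ipis_s=np.concatenate([b.ipis_s for b in bouts]),
        durations_s=np.array([b.duration_s for b in bouts]),
    )


def bout_onsets(bouts: list[Bout]) -> np.ndarray:
    """First-press time of each retained bout (the peri-event alignment point)."""
    return np.array([b.onset_s for b in bouts])


def classify_head_entries(events: EventStream):
    """Label each head entry as the outcome-retrieval entry or not.

    For each outcome, the earliest head entry after it and before the next
    outcome is ``first_after_outcome``; every other entry (including entries
    before any outcome) is ``non_rewarded``.  Outcomes with no intervening
    entry have no retrieval entry and are returned for logging.

    Returns ``(first_after_outcome_times, non_rewarded_times,
    unretrieved_outcome_times)``.
    """
    entries = events.times_of("head_entry")
    outcomes = events.times_of("outcome")
    first = []
    unretrieved = []
    taken = np.zeros(entries.size, dtype=bool)
    for i, out_t in enumerate(outcomes):
        next_out = outcomes[i + 1] if i + 1 < outcomes.size else np.inf
        cand = np.flatnonzero((entries > out_t) & (entries < next_out) & ~taken)
        if cand.size:
            taken[cand[0]] = True
            first.append(entries[cand[0]])
        else:
            unretrieved.append(out_t)
    non_rewarded = entries[~taken]
    return np.array(first), non_rewarded, np.array(unretrieved)
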