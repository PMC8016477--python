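"""Core in-memory containers for one animal-session.

Every container is a light dataclass over numpy arrays with validation at
construction; file I/O for each lives in :mod:`photoperant.io`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EVENT_KINDS = ("press", "head_entry", "outcome")

#: relative tolerance on inter-sample intervals for "uniformly sampled"
UNIFORMITY_RTOL = 1e-6


class ValidationError(ValueError):
    """Raised when a container's invariants are violated."""


@dataclass
class EventStream:
    """Timestamped behavioral events (lever presses, head entries, outcome
    deliveries) for one session, sorted by time."""

    times_s: np.ndarray
    kinds: np.ndarray
    session_id: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.kinds = np.asarray(self.kinds, dtype=object)
        if self.times_s.shape != self.kinds.shape:
            raise ValidationError("times and kinds must have equal length")
        unknown = set(self.kinds) - set(EVENT_KINDS)
        if unknown:
            raise ValidationError(f"unknown event kind(s): {sorted(unknown)}")
        if self.times_s.size and self.times_s.min() < 0:
            raise ValidationError("event times must be non-negative")
        order = np.argsort(self.times_s, kind="stable")
        self.times_s = self.times_s[order]
        self.kinds = self.kinds[order]

    def __len__(self) -> int:
        return self.times_s.size

    def times_of(self, kind: str) -> np.ndarray:
        if kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind: {kind!r}")
        return self.times_s[self.kinds == kind]

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventStream):
            return NotImplemented
        return (
            np.array_equal(self.times_s, other.times_s)
            and np.array_equal(self.kinds, other.kinds)
            and self.session_id == other.session_id
            and self.group_label == other.group_label
        )


def _check_uniform(time_s: np.ndarray) -> float:
    """Return the sampling rate, raising if sampling is non-uniform."""
    dt = np.diff(time_s)
    if dt.size == 0:
        raise ValidationError("need at least 2 samples")
    med = float(np.median(dt))
    if med <= 0:
        raise ValidationError("time axis must be strictly increasing")
    if np.max(np.abs(dt - med)) > UNIFORMITY_RTOL * med + 1e-12:
        raise ValidationError("non-uniform sampling beyond tolerance")
    return 1.0 / med


@dataclass
class RawPhotometrySession:
    """Raw fluorescence trace (arbitrary units) plus its aligned events."""

    time_s: np.ndarray
    fluorescence: np.ndarray
    sampling_rate_hz: float
    events: EventStream | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time_s.shape != self.fluorescence.shape:
            raise ValidationError("time and fluorescence must have equal length")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValidationError("fluorescence must be finite")
        fs = _check_uniform(self.time_s)
        if not np.isclose(fs, self.sampling_rate_hz, rtol=1e-3):
            raise ValidationError(
                f"declared rate {self.sampling_rate_hz} Hz inconsistent with "
                f"time axis ({fs:.6g} Hz)"
            )

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass
class OrientationTrace:
    """Head-orientation samples in radians, wrapped to (-pi, pi] or unwrapped."""

    time_s: np.ndarray
    orientation_rad: np.ndarray
    wrapped: bool = False

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.orientation_rad = np.asarray(self.orientation_rad, dtype=float)
        if self.time_s.shape != self.orientation_rad.shape:
            raise ValidationError("time and orientation must have equal length")
        if not np.all(np.isfinite(self.orientation_rad)):
            raise ValidationError("orientation must be finite")
        if self.time_s.size > 1 and np.any(np.diff(self.time_s) <= 0):
            raise ValidationError("time axis must be strictly increasing")


@dataclass
class EPSCSeries:
    """Evoked EPSC amplitude series with protocol landmarks.

    ``time`` is in minutes for slow (LTD-style, 0.05 Hz) recordings and in
    seconds within-trial for DSE-style recordings; ``time_unit`` records which.
    ``epoch_marks`` maps landmark names (e.g. ``baseline_end``,
    ``depolarization_start``/``_end``) to times in the same unit.
    """

    time: np.ndarray
    amplitude_pA: np.ndarray
    time_unit: str = "min"
    trial_id: np.ndarray | None = None
    epoch_marks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.amplitude_pA = np.asarray(self.amplitude_pA, dtype=float)
        if self.time.shape != self.amplitude_pA.shape:
            raise ValidationError("time and amplitude must have equal length")
        if np.any(self.amplitude_pA < 0):
            raise ValidationError("amplitudes must be non-negative")
        if self.time_unit not in ("min", "s"):
            raise ValidationError("time_unit must be 'min' or 's'")
        if self.trial_id is None:
            self.trial_id = np.zeros(self.time.shape, dtype=int)
        else:
            self.trial_id = np.asarray(self.trial_id, dtype=int)
            if self.trial_id.shape != self.time.shape:
                raise ValidationError("trial_id must match series length")
        if self.time.size:
            lo, hi = self.time.min(), self.time.max()
            for name, t in self.epoch_marks.items():
                if not (lo <= t <= hi + 1e-9):
                    raise ValidationError(
                        f"epoch mark {name!r}={t} outside series span [{lo}, {hi}]"
                    )

    def trials(self):
        """Yield (trial_id, time, amplitude) for each trial in order."""
        for tid in np.unique(self.trial_id):
            m = self.trial_id == tid
            yield int(tid), self.time[m], self.amplitude_pA[m]
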