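"""Rotation counting from a head-orientation trace.

A single running accumulator sums the frame-to-frame angular differences; a
clockwise rotation is counted (and the accumulator reset to 0) when the sum
reaches +6.28 rad, a counter-clockwise one when it reaches -6.28 rad.  The
threshold is deliberately 6.28, not 2*pi: the 0.003 rad difference matters
for exact-full-turn edge cases and is kept configurable.

Wrapped traces (tracker output in (-pi, pi]) are unwrapped before
differencing; any jump larger than pi between frames is interpreted as a
wrap.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import OrientationTrace


@dataclass
class RotationCounts:
    cw: int
    ccw: int

    @property
    def total(self) -> int:
        return self.cw + self.ccw

    @property
    def percent_cw(self) -> float:
        return percent_cw(self)


def count_rotations(
    trace: OrientationTrace | np.ndarray,
    threshold_rad: float = 6.28,
    mode: str = "shared",
) -> RotationCounts:
    """Count full CW (+) and CCW (-) rotations with the accumulator rule.

    ``mode="shared"`` is the literal single-accumulator reading: progress
    toward one direction is eroded by movement in the other.  The
    ``"independent"`` variant keeps one accumulator per direction, each
    floored at zero from the opposite side.
    """
    angles = trace.orientation_rad if isinstance(trace, OrientationTrace) else np.asarray(trace, dtype=float)
    if angles.size < 2:
        return RotationCounts(0, 0)
    diffs = np.diff(np.unwrap(angles))

    cw = ccw = 0
    if mode == "shared":
        acc = 0.0
        for d in diffs:
            acc += d
            if acc >= threshold_rad:
                cw += 1
                acc = 0.0
            elif acc <= -threshold_rad:
                ccw += 1
                acc = 0.0
    elif mode == "independent":
        acc_cw = acc_ccw = 0.0
        for d in diffs:
            acc_cw = max(acc_cw + d, 0.0)
            acc_ccw = min(acc_ccw + d, 0.0)
            if acc_cw >= threshold_rad:
                cw += 1
                acc_cw = 0.0
            if acc_ccw <= -threshold_rad:
                ccw += 1
                acc_ccw = 0.0
    else:
        raise ValueError(f"unknown rotation mode {mode!r}")
    return RotationCounts(cw, ccw)


def percent_cw(counts: RotationCounts) -> float:
    """100 * cw / (cw + ccw); NaN (flagged by the caller) when no rotations."""
    if counts.total == 0:
        return float("nan")
    return 100.0 * counts.cw / counts.total
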