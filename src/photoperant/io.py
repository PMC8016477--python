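"""Plain-CSV readers and writers for every container.

All four data files are single-purpose comma-separated tables with one header
row; session and group metadata travel in a separate manifest file.  Writers
emit full float precision so that every write/read pair is a lossless round
trip.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    EVENT_KINDS,
    EPSCSeries,
    EventStream,
    OrientationTrace,
    RawPhotometrySession,
    ValidationError,
    _check_uniform,
)


class ParseError(ValueError):
    """Raised for malformed rows; the message names the offending line."""


def _read_table(path, columns):
    path = Path(path)
    try:
        # round_trip parsing keeps write/read pairs lossless at 1e-9 and below
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty (no header row)")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    return df


def _numeric(df, col, path):
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = np.flatnonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())
    nan_src = np.flatnonzero(df[col].isna().to_numpy())
    bad = np.concatenate([bad, nan_src])
    if bad.size:
        # +2: one for the header row, one for 1-based numbering
        raise ParseError(f"{path}: non-numeric value in column {col!r} at line {int(bad.min()) + 2}")
    return vals.to_numpy(dtype=float)


# -- events ------------------------------------------------------------------

def read_events(path, session_id: str = "", group_label: str = "") -> EventStream:
    df = _read_table(path, ["time_s", "kind"])
    if df.empty:
        return EventStream(np.array([]), np.array([], dtype=object),
                           session_id=session_id, group_label=group_label)
    times = _numeric(df, "time_s", path)
    kinds = df["kind"].astype(str).to_numpy(dtype=object)
    unknown = np.flatnonzero(~np.isin(kinds, EVENT_KINDS))
    if unknown.size:
        raise ValidationError(
            f"{path}: unknown event kind {kinds[unknown[0]]!r} at line {int(unknown[0]) + 2}"
        )
    return EventStream(times, kinds, session_id=session_id, group_label=group_label)


def write_events(stream: EventStream, path) -> None:
    pd.DataFrame({"time_s": stream.times_s, "kind": stream.kinds}).to_csv(path, index=False)


# -- photometry trace ---------------------------------------------------------

def read_trace(path, events: EventStream | None = None) -> RawPhotometrySession:
    df = _read_table(path, ["time_s", "fluorescence"])
    if len(df) < 2:
        raise ValidationError(f"{path}: need at least 2 samples")
    t = _numeric(df, "time_s", path)
    f = _numeric(df, "fluorescence", path)
    fs = _check_uniform(t)  # raises on jittered timestamps
    return RawPhotometrySession(t, f, sampling_rate_hz=fs, events=events)


def write_trace(session: RawPhotometrySession, path) -> None:
    pd.DataFrame({"time_s": session.time_s, "fluorescence": session.fluorescence}).to_csv(
        path, index=False
    )


# -- orientation --------------------------------------------------------------

def read_orientation(path, wrapped: bool | None = None) -> OrientationTrace:
    df = _read_table(path, ["time_s", "orientation_rad"])
    if len(df) < 1:
        return OrientationTrace(np.array([]), np.array([]))
    t = _numeric(df, "time_s", path)
    a = _numeric(df, "orientation_rad", path)
    if wrapped is None:
        wrapped = bool(np.all(np.abs(a) <= np.pi + 1e-9))
    return OrientationTrace(t, a, wrapped=wrapped)


def write_orientation(trace: OrientationTrace, path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "orientation_rad": trace.orientation_rad}).to_csv(
        path, index=False
    )


# -- EPSC series ---------------------------------------------------------------

def read_epsc(path, time_unit: str = "min", epoch_marks: dict | None = None) -> EPSCSeries:
    df = _read_table(path, ["time", "amplitude_pA"])
    t = _numeric(df, "time", path)
    a = _numeric(df, "amplitude_pA", path)
    tid = (
        _numeric(df, "trial_id", path).astype(int)
        if "trial_id" in df.columns
        else None
    )
    return EPSCSeries(t, a, time_unit=time_unit, trial_id=tid,
                      epoch_marks=epoch_marks or {})


def write_epsc(series: EPSCSeries, path) -> None:
    pd.DataFrame(
        {"time": series.time, "amplitude_pA": series.amplitude_pA, "trial_id": series.trial_id}
    ).to_csv(path, index=False)


# -- derived products ----------------------------------------------------------

def write_dff(dff, path) -> None:
    """dF/F0 table: time_s, dff, f0 (see photometry.DffTrace)."""
    pd.DataFrame({"time_s": dff.time_s, "dff": dff.dff, "f0": dff.f0}).to_csv(
        path, index=False
    )


def read_dff(path):
    from .photometry import DffTrace

    df = _read_table(path, ["time_s", "dff"])
    if len(df) < 2:
        raise ValidationError(f"{path}: need at least 2 samples")
    t = _numeric(df, "time_s", path)
    fs = _check_uniform(t)
    f0 = _numeric(df, "f0", path) if "f0" in df.columns else np.full(t.size, np.nan)
    return DffTrace(t, _numeric(df, "dff", path), f0, sampling_rate_hz=fs)


def write_tensor(tensor, path) -> None:
    """Peri-event tensor: one row per trial; z columns named by bin center."""
    cols = {"session_id": tensor.session_ids, "event_time_s": tensor.event_times_s}
    for j, c in enumerate(tensor.bin_centers_s):
        cols[f"z_{c:.4f}"] = tensor.z[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_tensor(path, event_type: str = "",
                baseline_window=(-5.0, -2.0), analysis_window=(-2.0, 2.0)):
    from .perievent import PeriEventTensor

    df = pd.read_csv(path)
    zcols = [c for c in df.columns if c.startswith("z_")]
    if not zcols:
        raise ParseError(f"{path}: no z_* columns found")
    centers = np.array([float(c[2:]) for c in zcols])
    return PeriEventTensor(
        z=df[zcols].to_numpy(dtype=float),
        bin_centers_s=centers,
        event_type=event_type,
        session_ids=df["session_id"].astype(str).to_numpy(dtype=object)
        if "session_id" in df.columns else np.array([], dtype=object),
        event_times_s=df["event_time_s"].to_numpy(dtype=float)
        if "event_time_s" in df.columns else np.full(len(df), np.nan),
        baseline_window_s=baseline_window,
        analysis_window_s=analysis_window,
    )


# -- manifest ------------------------------------------------------------------

def read_manifest(path) -> pd.DataFrame:
    """Manifest: one row per session with columns
    session_id, group, trace_path, events_path (paths relative to the manifest)."""
    df = _read_table(path, ["session_id", "group", "trace_path", "events_path"])
    base = Path(path).parent
    for col in ("trace_path", "events_path"):
        df[col] = [str((base / p)) if not Path(p).is_absolute() else p for p in df[col]]
    return df
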