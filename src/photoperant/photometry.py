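"""Raw fluorescence -> QC'd dF/F0.

The preprocessing chain for a bulk calcium (GCaMP6s) fiber-photometry trace:

1. fit a double exponential F_hat(t) = A1*exp(-t/tau1) + A2*exp(-t/tau2) to the
   raw trace to capture photobleaching and signal decay, and divide the trace
   by the fit (the normalized trace is unitless and trend-free);
2. estimate a running baseline F0 as the 10th percentile of the normalized
   trace in a centered 15 s sliding window;
3. dF/F0 = (normalized - F0) / F0;
4. session QC: keep the session only if the 97.5th percentile of dF/F0 over
   the whole trace exceeds a 1% change from baseline.

No isosbestic reference channel is used anywhere in this chain; GCaMP6s has an
excitation peak in the 405-410 nm band, so a "calcium-independent" reference
is not available for this indicator.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import least_squares

from .config import ConfigError, PipelineConfig
from .datatypes import RawPhotometrySession


class PhotometryError(ValueError):
    pass


@dataclass
class BleachFit:
    """Double-exponential photobleaching fit and the trend-normalized trace."""

    A1: float
    tau1_s: float
    A2: float
    tau2_s: float
    fitted: np.ndarray
    normalized: np.ndarray
    residual_rms: float
    degenerate: bool = False
    single_exponential: bool = False

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.A1 * np.exp(-t / self.tau1_s) + self.A2 * np.exp(-t / self.tau2_s)


@dataclass
class DffTrace:
    """dF/F0 trace with its baseline and session-level QC verdict."""

    time_s: np.ndarray
    dff: np.ndarray
    f0: np.ndarray
    sampling_rate_hz: float
    qc_passed: bool = True
    qc_value: float = np.nan


def _double_exp(params, t):
    a1, t1, a2, t2 = params
    return a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2)


def fit_double_exponential(session: RawPhotometrySession) -> BleachFit:
    """Fit the photobleaching trend and normalize the trace to it.

    Uses multi-start robust (soft-L1) least squares so that event-locked
    transients, which sit above the bleach envelope, have little leverage on
    the trend estimate.  Falls back to a single exponential (with a warning)
    if no double-exponential start converges; an all-constant trace yields a
    degenerate fit with ``normalized = F / mean(F)``.
    """
    t = session.time_s - session.time_s[0]
    f = session.fluorescence
    if t.size < 100:
        raise PhotometryError("need at least 100 samples to fit a bleach trend")
    if np.any(f <= 0):
        raise PhotometryError("fluorescence must be strictly positive")

    mean_f = float(np.mean(f))
    if np.ptp(f) <= 1e-12 * max(mean_f, 1.0):
        fitted = np.full_like(f, mean_f)
        return BleachFit(mean_f, np.inf, 0.0, np.inf, fitted, f / mean_f,
                         residual_rms=0.0, degenerate=True)

    head = float(np.mean(f[: max(1, f.size // 20)]))
    tail = float(np.mean(f[-max(1, f.size // 20):]))
    f_scale = max(1e-3 * mean_f, 1e-12)
    span = float(t[-1])
    bounds = ([0.0, 1e-2, 0.0, 1e-2], [np.inf, 1e7, np.inf, 1e7])

    best = None
    for tau1, tau2 in ((30.0, 300.0), (120.0, 1500.0), (span / 20, span)):
        a2_0 = max(tail, 1e-6 * mean_f)
        a1_0 = max(head - tail, 0.1 * mean_f)
        x0 = [a1_0, tau1, a2_0, tau2]
        try:
            res = least_squares(
                lambda p: _double_exp(p, t) - f, x0, bounds=bounds,
                loss="soft_l1", f_scale=f_scale, max_nfev=2000,
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res

    single = False
    if best is None:
        warnings.warn("double-exponential fit did not converge; "
                      "falling back to a single exponential")
        res = least_squares(
            lambda p: p[0] * np.exp(-t / p[1]) - f,
            [mean_f, max(span, 1.0)],
            bounds=([0.0, 1e-2], [np.inf, 1e7]),
            loss="soft_l1", f_scale=f_scale, max_nfev=2000,
        )
        params = [res.x[0], res.x[1], 0.0, np.inf]
        single = True
    else:
        params = list(best.x)

    a1, t1, a2, t2 = params
    fitted = a1 * np.exp(-t / t1) + (a2 * np.exp(-t / t2) if np.isfinite(t2) else 0.0)
    if np.any(fitted <= 0):
        fitted = np.full_like(f, mean_f)
        return BleachFit(mean_f, np.inf, 0.0, np.inf, fitted, f / mean_f,
                         residual_rms=float(np.sqrt(np.mean((f - mean_f) ** 2))),
                         degenerate=True)
    rms = float(np.sqrt(np.mean((f - fitted) ** 2)))
    return BleachFit(a1, t1, a2, t2, fitted, f / fitted, residual_rms=rms,
                     single_exponential=single)


def running_percentile_baseline(
    normalized: np.ndarray,
    sampling_rate_hz: float,
    window_s: float = 15.0,
    percentile: float = 10.0,
) -> np.ndarray:
    """Running percentile of the normalized trace in a centered window.

    The window is truncated (not padded) at the session edges.  The percentile
    uses numpy's linear interpolation between order statistics.
    """
    if window_s <= 0:
        raise ConfigError("window_s must be > 0")
    x = np.asarray(normalized, dtype=float)
    n = x.size
    half = int(round(window_s * sampling_rate_hz / 2.0))
    if half < 1 or 2 * half + 1 >= n:
        return np.full(n, np.percentile(x, percentile))

    w = 2 * half + 1
    out = np.empty(n)
    windows = sliding_window_view(x, w)          # window i covers [i, i+w)
    out[half: n - half] = np.percentile(windows, percentile, axis=1)
    for j in range(half):                         # truncated edge windows
        out[j] = np.percentile(x[: j + half + 1], percentile)
        out[n - 1 - j] = np.percentile(x[n - 1 - j - half:], percentile)
    return out


def compute_dff(normalized: np.ndarray, f0: np.ndarray) -> np.ndarray:
    """dF/F0 = (normalized - F0) / F0."""
    normalized = np.asarray(normalized, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    if normalized.shape != f0.shape:
        raise PhotometryError("normalized and F0 must have equal length")
    if np.any(f0 <= 0):
        raise PhotometryError("F0 must be strictly positive")
    return (normalized - f0) / f0


def session_qc(dff: np.ndarray, threshold: float = 0.01,
               percentile: float = 97.5) -> tuple[bool, float]:
    """Keep a session only if the session-wide 97.5th percentile of dF/F0
    exceeds a 1% change — i.e. the recording shows transients at all,
    independent of any behavioral alignment."""
    dff = np.asarray(dff, dtype=float)
    if dff.size == 0:
        raise PhotometryError("empty dF/F0 trace")
    q = float(np.percentile(dff, percentile))
    return q > threshold, q


def preprocess_session(session: RawPhotometrySession,
                       config: PipelineConfig | None = None) -> DffTrace:
    """Full chain: bleach fit -> running-percentile F0 -> dF/F0 -> QC."""
    cfg = config or PipelineConfig()
    fit = fit_double_exponential(session)
    f0 = running_percentile_baseline(
        fit.normalized, session.sampling_rate_hz,
        window_s=cfg.baseline_window_s, percentile=cfg.baseline_percentile,
    )
    dff = compute_dff(fit.normalized, f0)
    passed, qc_value = session_qc(dff, threshold=cfg.qc_threshold,
                                  percentile=cfg.qc_percentile)
    return DffTrace(session.time_s, dff, f0, session.sampling_rate_hz,
                    qc_passed=passed, qc_value=qc_value)
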