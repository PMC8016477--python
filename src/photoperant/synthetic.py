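"""Synthetic sessions with the statistical structure the analysis assumes.

Generators for every input the pipeline consumes: operant event streams under
a random-ratio schedule with bout-structured pressing, photometry traces with
double-exponential photobleaching and GCaMP6s-like event-locked transients,
orientation trajectories with planted full rotations, and evoked-EPSC series
with planted step depressions.  Group presets carry the study conditions
(e.g. within-bout inter-press interval 1.84 s in Air controls vs 1.31 s after
chronic intermittent ethanol) so downstream modules are exercisable end to
end without any external recording.

All generators are deterministic under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .config import ConfigError
from .datatypes import EPSCSeries, EventStream, OrientationTrace, RawPhotometrySession

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

@dataclass
class BehaviorSimConfig:
    """Operant session under random-ratio (RR) reinforcement.

    Pressing is organized into planted bouts: within-bout IPIs are truncated
    normal (lower bound 0.2 s) with the *truncated* mean equal to
    ``within_bout_ipi_mean_s``; bouts are separated by shifted-exponential
    gaps.  Each press is reinforced with probability 1/ratio; each outcome is
    followed by a retrieval head entry at a log-normal latency, and
    spontaneous (non-rewarded) head entries occur at a Poisson rate.  The
    session ends at ``max_reinforcers`` outcomes or ``session_length_s``,
    whichever comes first.
    """

    session_length_s: float = 3600.0
    max_reinforcers: int = 30
    ratio: float = 20.0                       # mean presses per reinforcer
    n_bouts: int = 45
    presses_per_bout_mean: float = 8.0
    within_bout_ipi_mean_s: float = 1.84
    within_bout_ipi_sd_s: float = 0.5
    ipi_lower_bound_s: float = 0.2
    between_bout_gap_mean_s: float = 60.0
    between_bout_gap_min_s: float = 10.0
    head_entry_latency_median_s: float = 1.2  # log-normal median
    head_entry_latency_sigma: float = 0.5     # log-normal shape
    spontaneous_entry_rate_hz: float = 0.01
    outcome_delivery_delay_s: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.session_length_s <= 0 or self.between_bout_gap_mean_s <= 0:
            raise ConfigError("durations must be > 0")
        if self.max_reinforcers < 1:
            raise ConfigError("max_reinforcers must be >= 1")
        if self.presses_per_bout_mean < 3:
            raise ConfigError("presses_per_bout_mean must be >= 3")
        if self.within_bout_ipi_mean_s <= self.ipi_lower_bound_s:
            raise ConfigError("within-bout IPI mean must exceed the lower bound")
        if self.within_bout_ipi_sd_s <= 0 or self.ratio < 1:
            raise ConfigError("invalid distribution parameters")
        if self.between_bout_gap_mean_s <= self.between_bout_gap_min_s:
            raise ConfigError("gap mean must exceed gap minimum")


def _truncnorm_loc(target_mean: float, sd: float, lower: float) -> float:
    """Location parameter of a lower-truncated normal whose truncated mean
    equals ``target_mean`` (compensates the truncation bias)."""
    def truncated_mean(mu):
        a = (lower - mu) / sd
        return stats.truncnorm.mean(a, np.inf, loc=mu, scale=sd) - target_mean

    lo = lower - 10 * sd
    hi = target_mean + sd
    return float(optimize.brentq(truncated_mean, lo, hi, xtol=1e-10))


def generate_behavior_session(
    cfg: BehaviorSimConfig, session_id: str = "", group_label: str = ""
) -> EventStream:
    """Simulate one operant session as a time-sorted event stream."""
    rng = np.random.default_rng(cfg.seed)
    mu = _truncnorm_loc(cfg.within_bout_ipi_mean_s, cfg.within_bout_ipi_sd_s,
                        cfg.ipi_lower_bound_s)
    a = (cfg.ipi_lower_bound_s - mu) / cfg.within_bout_ipi_sd_s

    presses, outcomes, entries = [], [], []
    t = 0.0
    n_reinforced = 0
    done = False
    for _ in range(cfg.n_bouts):
        gap = cfg.between_bout_gap_min_s + rng.exponential(
            cfg.between_bout_gap_mean_s - cfg.between_bout_gap_min_s
        )
        t += gap
        n_presses = max(1, int(rng.poisson(cfg.presses_per_bout_mean)))
        ipis = stats.truncnorm.ppf(
            rng.random(max(n_presses - 1, 0)), a, np.inf,
            loc=mu, scale=cfg.within_bout_ipi_sd_s,
        )
        for k in range(n_presses):
            if k > 0:
                t += ipis[k - 1]
            if t > cfg.session_length_s:
                done = True
                break
            presses.append(t)
            if rng.random() < 1.0 / cfg.ratio:
                t_out = t + cfg.outcome_delivery_delay_s
                outcomes.append(t_out)
                latency = rng.lognormal(np.log(cfg.head_entry_latency_median_s),
                                        cfg.head_entry_latency_sigma)
                entries.append(t_out + latency)
                n_reinforced += 1
                if n_reinforced >= cfg.max_reinforcers:
                    done = True
                    break
        if done:
            break

    session_end = min(cfg.session_length_s,
                      outcomes[-1] if n_reinforced >= cfg.max_reinforcers else cfg.session_length_s)
    # retrieval entries may trail the final outcome slightly; keep them
    if cfg.spontaneous_entry_rate_hz > 0:
        n_spont = rng.poisson(cfg.spontaneous_entry_rate_hz * session_end)
        entries.extend(rng.uniform(0, session_end, size=n_spont))

    times = np.array(presses + entries + outcomes)
    kinds = np.array(
        ["press"] * len(presses) + ["head_entry"] * len(entries)
        + ["outcome"] * len(outcomes), dtype=object,
    )
    return EventStream(times, kinds, session_id=session_id, group_label=group_label)


def air_behavior_config(seed: int = 0, **overrides) -> BehaviorSimConfig:
    """Air-control study conditions (within-bout IPI 1.84 s, ~41 bouts)."""
    kw = dict(within_bout_ipi_mean_s=1.84, within_bout_ipi_sd_s=0.5, n_bouts=41, seed=seed)
    kw.update(overrides)
    return BehaviorSimConfig(**kw)


def cie_behavior_config(seed: int = 0, **overrides) -> BehaviorSimConfig:
    """Chronic-intermittent-ethanol conditions (IPI 1.31 s, ~50 bouts)."""
    kw = dict(within_bout_ipi_mean_s=1.31, within_bout_ipi_sd_s=0.35, n_bouts=50, seed=seed)
    kw.update(overrides)
    return BehaviorSimConfig(**kw)


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------

@dataclass
class PhotometrySimConfig:
    """Bleaching envelope x (1 + event-locked transients) + Gaussian noise.

    The transient kernel is a peak-normalized difference of exponentials
    (rise 0.2 s, decay 1.5 s) emulating a GCaMP6s response; responses add
    linearly and are scaled per event type by ``event_response_amp``
    (fractional amplitude relative to the local bleach envelope).  The bleach
    envelope is a double exponential plus a constant floor, sized so a 1 hr
    session loses roughly 30% of its initial intensity by default.
    """

    sampling_rate_hz: float = 20.0
    duration_s: float | None = None           # default: last event + 10 s
    bleach_amp1: float = 0.1
    bleach_tau1_s: float = 120.0
    bleach_amp2: float = 0.2
    bleach_tau2_s: float = 1500.0
    bleach_floor: float = 0.7
    base_intensity: float = 100.0             # arbitrary camera units
    kernel_rise_s: float = 0.2
    kernel_decay_s: float = 1.5
    event_response_amp: dict = field(
        default_factory=lambda: {"press": 0.02, "head_entry": 0.05, "outcome": 0.03}
    )
    noise_sd: float = 0.005                   # fraction of local baseline
    # spontaneous (non-event-locked) transients: the ongoing population
    # activity that gives real recordings their baseline variability; off by
    # default so noise-free traces reduce exactly to the bleach envelope
    spontaneous_rate_hz: float = 0.0
    spontaneous_amp: float = 0.03             # lognormal median amplitude
    spontaneous_amp_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ConfigError("sampling_rate_hz must be > 0")
        if min(self.bleach_tau1_s, self.bleach_tau2_s,
               self.kernel_rise_s, self.kernel_decay_s) <= 0:
            raise ConfigError("time constants must be > 0")
        if self.kernel_decay_s <= self.kernel_rise_s:
            raise ConfigError("kernel decay must exceed rise")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.spontaneous_rate_hz < 0:
            raise ConfigError("spontaneous_rate_hz must be >= 0")
        if self.bleach_amp1 < 0 or self.bleach_amp2 < 0 or self.bleach_floor < 0:
            raise ConfigError("bleach amplitudes must be >= 0")
        if self.bleach_amp1 + self.bleach_amp2 + self.bleach_floor <= 0:
            raise ConfigError("bleach envelope must be positive")


def transient_kernel(cfg: PhotometrySimConfig, t: np.ndarray) -> np.ndarray:
    """Peak-normalized difference-of-exponentials kernel on t >= 0."""
    tr, td = cfg.kernel_rise_s, cfg.kernel_decay_s
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / td) - np.exp(-np.maximum(t, 0) / tr), 0.0)
    t_peak = np.log(td / tr) / (1.0 / tr - 1.0 / td)
    peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    return k / peak


def bleach_envelope(cfg: PhotometrySimConfig, t: np.ndarray) -> np.ndarray:
    return cfg.base_intensity * (
        cfg.bleach_amp1 * np.exp(-t / cfg.bleach_tau1_s)
        + cfg.bleach_amp2 * np.exp(-t / cfg.bleach_tau2_s)
        + cfg.bleach_floor
    )


def generate_photometry_trace(
    events: EventStream, cfg: PhotometrySimConfig
) -> RawPhotometrySession:
    """trace = bleach(t) * (1 + sum of event-locked kernels + noise)."""
    if cfg.duration_s is not None:
        duration = cfg.duration_s
    elif len(events):
        duration = float(events.times_s[-1]) + 10.0
    else:
        duration = 60.0
    if len(events) and events.times_s[-1] > duration:
        raise ConfigError("events extend beyond the trace duration")

    fs = cfg.sampling_rate_hz
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs

    rng = np.random.default_rng(cfg.seed)
    response = np.zeros(n)
    k_len = int(round(8.0 * cfg.kernel_decay_s * fs)) + 1

    def add_kernel(te, amp):
        i0 = int(np.ceil(te * fs - 1e-9))
        i1 = min(i0 + k_len, n)
        if i0 < n:
            response[i0:i1] += amp * transient_kernel(cfg, t[i0:i1] - te)

    for te, kind in zip(events.times_s, events.kinds):
        amp = cfg.event_response_amp.get(kind, 0.0)
        if amp != 0.0:
            add_kernel(te, amp)
    if cfg.spontaneous_rate_hz > 0:
        n_spont = rng.poisson(cfg.spontaneous_rate_hz * duration)
        spont_times = np.sort(rng.uniform(0.0, duration, size=n_spont))
        spont_amps = rng.lognormal(np.log(cfg.spontaneous_amp),
                                   cfg.spontaneous_amp_sigma, size=n_spont)
        for te, amp in zip(spont_times, spont_amps):
            add_kernel(te, amp)
    noise = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else 0.0
    f = bleach_envelope(cfg, t) * (1.0 + response + noise)
    return RawPhotometrySession(t, f, sampling_rate_hz=fs, events=events)


def air_photometry_config(seed: int = 0, **overrides) -> PhotometrySimConfig:
    """Robust outcome-retrieval transients (intact outcome encoding)."""
    kw = dict(event_response_amp={"press": 0.015, "head_entry": 0.06, "outcome": 0.03},
              spontaneous_rate_hz=0.1, seed=seed)
    kw.update(overrides)
    return PhotometrySimConfig(**kw)


def cie_photometry_config(seed: int = 0, **overrides) -> PhotometrySimConfig:
    """Blunted outcome-retrieval transients, slightly larger press response."""
    kw = dict(event_response_amp={"press": 0.02, "head_entry": 0.015, "outcome": 0.01},
              spontaneous_rate_hz=0.1, seed=seed)
    kw.update(overrides)
    return PhotometrySimConfig(**kw)


# ---------------------------------------------------------------------------
# peri-event trial matrices (direct route for statistical calibration)
# ---------------------------------------------------------------------------

def generate_perievent_trials(
    n_trials: int,
    response_amp: float = 0.0,
    response_window: tuple[float, float] = (0.0, 1.0),
    noise_sd: float = 1.0,
    window: tuple[float, float] = (-5.0, 5.0),
    bin_s: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw peri-event trial matrix: i.i.d. Gaussian bins plus an optional
    constant offset planted in ``response_window``.

    This is the direct route for calibrating the permutation machinery: with
    ``noise_sd=1`` the planted offset is (after baseline z-scoring) the
    response size in z units.  Returns ``(raw_matrix, bin_centers)``.
    """
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    if noise_sd <= 0:
        raise ConfigError("noise_sd must be > 0")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n_bins = int(round((window[1] - window[0]) / bin_s))
    centers = window[0] + (np.arange(n_bins) + 0.5) * bin_s
    raw = rng.normal(0.0, noise_sd, size=(n_trials, n_bins))
    if response_amp != 0.0:
        m = (centers >= response_window[0]) & (centers < response_window[1])
        raw[:, m] += response_amp
    return raw, centers


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

@dataclass
class OrientationSimConfig:
    """Planted full rotations: n_cw clockwise (+2*pi) and n_ccw
    counter-clockwise (-2*pi) turns in a randomized order, linear ramps with
    stationary pauses between turns, optional per-frame angular jitter, and
    optional wrapping to (-pi, pi]."""

    frame_rate_hz: float = 30.0
    n_cw: int = 0
    n_ccw: int = 0
    turn_duration_s: float = 2.0
    pause_s: float = 1.0
    jitter_sd_rad: float = 0.0
    wrap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cw < 0 or self.n_ccw < 0:
            raise ConfigError("rotation counts must be >= 0")
        if self.frame_rate_hz <= 0 or self.turn_duration_s <= 0 or self.pause_s < 0:
            raise ConfigError("invalid timing parameters")
        if self.jitter_sd_rad < 0:
            raise ConfigError("jitter_sd_rad must be >= 0")


def generate_orientation_trace(cfg: OrientationSimConfig) -> OrientationTrace:
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.frame_rate_hz
    turn_frames = max(2, int(round(cfg.turn_duration_s * fs)))
    pause_frames = int(round(cfg.pause_s * fs))

    directions = np.array([1] * cfg.n_cw + [-1] * cfg.n_ccw)
    rng.shuffle(directions)

    segments = [np.zeros(pause_frames)]
    for d in directions:
        segments.append(np.full(turn_frames, d * TWO_PI / turn_frames))
        segments.append(np.zeros(pause_frames))
    increments = np.concatenate(segments) if segments else np.zeros(1)
    angle = np.concatenate([[0.0], np.cumsum(increments)])
    if cfg.jitter_sd_rad > 0:
        angle = angle + rng.normal(0.0, cfg.jitter_sd_rad, size=angle.size)
    t = np.arange(angle.size) / fs
    if cfg.wrap:
        wrapped = np.mod(angle + np.pi, TWO_PI) - np.pi
        return OrientationTrace(t, wrapped, wrapped=True)
    return OrientationTrace(t, angle, wrapped=False)


# ---------------------------------------------------------------------------
# ephys
# ---------------------------------------------------------------------------

@dataclass
class EphysSimConfig:
    """Evoked-EPSC series with a planted depression.

    ``protocol="LTD"``: 0.05 Hz sweeps over 40 min; amplitude steps to
    ``depression_fraction * baseline`` at ``onset_time`` (minutes).
    ``protocol="DSE"``: three trials of 0.2 Hz sweeps — 30 s baseline, 10 s
    depolarization gap, 120 s recovery — with an immediate dip to
    ``depression_fraction`` that recovers exponentially (tau 20 s).
    """

    protocol: str = "LTD"
    baseline_amp_pA: float = 200.0
    depression_fraction: float = 0.55
    onset_time: float = 10.0                  # minutes (LTD); DSE uses the gap
    noise_sd_pA: float = 0.0
    recovery_tau_s: float = 20.0              # DSE only
    n_trials: int = 3                         # DSE only
    duration_min: float = 40.0                # LTD only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protocol not in ("LTD", "DSE"):
            raise ConfigError(f"unknown protocol {self.protocol!r}")
        if not 0 <= self.depression_fraction <= 1.5:
            raise ConfigError("depression_fraction must be in [0, 1.5]")
        if self.baseline_amp_pA <= 0:
            raise ConfigError("baseline_amp_pA must be > 0")
        if self.noise_sd_pA < 0:
            raise ConfigError("noise_sd_pA must be >= 0")


def generate_epsc_series(cfg: EphysSimConfig) -> EPSCSeries:
    rng = np.random.default_rng(cfg.seed)
    if cfg.protocol == "LTD":
        # 0.05 Hz -> one sweep every 20 s = 1/3 min
        t_min = np.arange(0.0, cfg.duration_min + 1e-9, 1.0 / 3.0)
        amp = np.where(t_min < cfg.onset_time, cfg.baseline_amp_pA,
                       cfg.depression_fraction * cfg.baseline_amp_pA)
        if cfg.noise_sd_pA > 0:
            amp = amp + rng.normal(0.0, cfg.noise_sd_pA, size=amp.size)
        amp = np.maximum(amp, 0.0)
        return EPSCSeries(
            t_min, amp, time_unit="min",
            epoch_marks={"baseline_end": cfg.onset_time,
                         "induction_start": cfg.onset_time},
        )

    # DSE: per-trial relative time axis in seconds
    t_base = np.arange(0.0, 30.0, 5.0)                 # 6 baseline sweeps
    t_post = 40.0 + np.arange(0.0, 120.0 + 1e-9, 5.0)  # recovery sweeps
    times, amps, trials = [], [], []
    for trial in range(cfg.n_trials):
        base = np.full(t_base.size, cfg.baseline_amp_pA)
        recovery = cfg.baseline_amp_pA * (
            1.0 - (1.0 - cfg.depression_fraction)
            * np.exp(-(t_post - 40.0) / cfg.recovery_tau_s)
        )
        a = np.concatenate([base, recovery])
        if cfg.noise_sd_pA > 0:
            a = a + rng.normal(0.0, cfg.noise_sd_pA, size=a.size)
        times.append(np.concatenate([t_base, t_post]))
        amps.append(np.maximum(a, 0.0))
        trials.append(np.full(t_base.size + t_post.size, trial))
    return EPSCSeries(
        np.concatenate(times), np.concatenate(amps), time_unit="s",
        trial_id=np.concatenate(trials),
        epoch_marks={"baseline_end": 30.0, "depolarization_start": 30.0,
                     "depolarization_end": 40.0},
    )


# study-condition ephys presets ------------------------------------------------

def ltd_config(group: str = "air", seed: int = 0, **overrides) -> EphysSimConfig:
    """DHPG-LTD conditions: EPSCs settle to 54.6% (Air) / 46.7% (CIE) of baseline."""
    frac = {"air": 0.546, "cie": 0.4668}[group.lower()]
    kw = dict(protocol="LTD", depression_fraction=frac, seed=seed)
    kw.update(overrides)
    return EphysSimConfig(**kw)


def dse_config(group: str = "air", seed: int = 0, **overrides) -> EphysSimConfig:
    """DSE conditions: first-point suppression 25.78% (Air) / 42.10% (CIE)."""
    frac = {"air": 1.0 - 0.2578, "cie": 1.0 - 0.4210}[group.lower()]
    kw = dict(protocol="DSE", depression_fraction=frac, seed=seed)
    kw.update(overrides)
    return EphysSimConfig(**kw)


def rotation_config(group: str = "air", seed: int = 0, **overrides) -> OrientationSimConfig:
    """Unilateral D1-agonist rotation conditions: Air mice strongly biased
    clockwise (~74% CW of ~61 turns); CIE mice near chance (~48% of ~58)."""
    n_cw, n_ccw = {"air": (45, 16), "cie": (28, 30)}[group.lower()]
    kw = dict(n_cw=n_cw, n_ccw=n_ccw, seed=seed)
    kw.update(overrides)
    return OrientationSimConfig(**kw)
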