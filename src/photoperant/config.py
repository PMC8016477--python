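"""Flat pipeline configuration with documented defaults.

Every tunable of every analysis stage lives here as one key so a whole run is
reproducible from a single YAML document plus the input files.  Unknown keys
are rejected rather than ignored.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration values."""


@dataclass
class PipelineConfig:
    # photometry preprocessing
    baseline_window_s: float = 15.0      # sliding window for the running-percentile F0
    baseline_percentile: float = 10.0    # percentile defining F0
    qc_percentile: float = 97.5          # session QC: percentile of dF/F0 examined
    qc_threshold: float = 0.01           # ... must exceed this (1% change)

    # peri-event extraction
    window_start_s: float = -5.0
    window_end_s: float = 5.0
    bin_s: float = 0.05
    baseline_start_s: float = -5.0       # z-scoring baseline window
    baseline_end_s: float = -2.0
    analysis_start_s: float = -2.0       # analysis window for AUC / statistics
    analysis_end_s: float = 2.0
    per_trial_zscore: bool = False       # sensitivity switch; default pools per session
    outlier_k: float = 3.0               # fences at median +/- k * scaled MAD
    mad_scale: float = 1.4826            # normal-consistency constant

    # group statistics
    n_permutations: int = 1000
    alpha: float = 0.05
    min_run: int = 4                     # consecutive significant bins required

    # behavior
    min_bout_presses: int = 3

    # rotation assay
    rotation_threshold_rad: float = 6.28
    rotation_mode: str = "shared"        # "shared" or "independent" accumulator

    # ephys
    epsc_baseline_min: float = 10.0
    epsc_bin_min: float = 2.0
    ltd_start_min: float = 30.0
    ltd_end_min: float = 40.0
    spike_threshold_mV: float = 0.0
    spike_refractory_s: float = 0.002

    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_window_s <= 0:
            raise ConfigError("baseline_window_s must be > 0")
        if not 0 < self.baseline_percentile < 100:
            raise ConfigError("baseline_percentile must be in (0, 100)")
        if self.bin_s <= 0:
            raise ConfigError("bin_s must be > 0")
        if not (self.window_start_s <= self.baseline_start_s < self.baseline_end_s
                <= self.window_end_s):
            raise ConfigError("baseline window must lie inside the peri-event window")
        if not (self.window_start_s <= self.analysis_start_s < self.analysis_end_s
                <= self.window_end_s):
            raise ConfigError("analysis window must lie inside the peri-event window")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.min_run < 1:
            raise ConfigError("min_run must be >= 1")
        if self.rotation_mode not in ("shared", "independent"):
            raise ConfigError("rotation_mode must be 'shared' or 'independent'")
        if self.rotation_threshold_rad <= 0:
            raise ConfigError("rotation_threshold_rad must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError("configuration file must contain a mapping")
        return cls.from_dict(doc)

    def to_dict(self) -> dict:
        return asdict(self)
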