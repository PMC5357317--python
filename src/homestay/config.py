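"""Study configuration: simulation parameters and pipeline thresholds.

All knobs live in one flat key/value file (YAML mapping, one level deep).
``SimConfig`` holds everything the cohort simulator needs; ``PipelineConfig``
holds the preprocessing / feature / model thresholds.  Keys shared by both
(``gps_interval``, ``timezone``) may appear once in the file and are routed
to both objects.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

__all__ = ["SimConfig", "PipelineConfig", "load_config", "dump_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for malformed or out-of-range configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters for the synthetic cohort generator."""

    n_participants: int = 60
    n_days: int = 14
    start_date: str = "2017-02-06"
    timezone: str = "America/New_York"
    # GPS sampling
    gps_interval: float = 150.0          # seconds between fixes
    gps_noise_sd: float = 10.0           # metres, isotropic jitter
    missing_rate: float = 0.10           # long-run fraction of time in gap runs
    missing_gap_mean_s: float = 1800.0   # mean length of a contiguous gap run
    # EMA prompting
    prompts_per_day_max: int = 6
    compliance_rate: float = 0.42
    # Latent affect model
    coupling_na: float = 0.0             # VAS shift per unit of home propensity
    coupling_pa: float = 0.0
    moderation_na_sias: float = 0.0      # extra NA coupling per SD of SIAS
    moderation_pa_sias: float = 0.0
    coupling_lag: int = 0                # affect on day d reads propensity of day d+lag
    affect_noise_sd: float = 10.0
    baseline_na_mean: float = 35.0
    baseline_pa_mean: float = 55.0
    baseline_sd: float = 6.0
    intercept_sd: float = 8.0            # SD of per-person random intercepts
    # Trait instruments
    sias_mean: float = 29.9
    sias_sd: float = 9.6
    dass_mean: float = 3.3
    dass_sd: float = 2.4
    # Mobility
    away_prob: float = 0.9               # P(leave home at all on a day)
    zero_home_prob: float = 0.30         # P(no daytime homestay | leaves home)
    home_propensity_mean: float = 0.5
    home_propensity_sd: float = 0.25
    trait_propensity_sias: float = 0.0   # propensity shift per SD of SIAS
    night_at_home: bool = True
    n_away_places: int = 3
    center_lat: float = 38.035
    center_lon: float = -78.503
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        if self.gps_interval <= 0:
            raise ConfigError("gps_interval must be > 0")
        if self.prompts_per_day_max < 1:
            raise ConfigError("prompts_per_day_max must be >= 1")
        for name in ("missing_rate", "compliance_rate", "away_prob",
                     "zero_home_prob", "home_propensity_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("gps_noise_sd", "affect_noise_sd", "sias_sd", "dass_sd",
                     "intercept_sd", "baseline_sd", "home_propensity_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.coupling_lag not in (-1, 0, 1):
            raise ConfigError("coupling_lag must be -1, 0 or +1")
        return self


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds for preprocessing, feature building and model fitting."""

    timezone: str = "America/New_York"
    gps_interval: float = 150.0
    # stay detection
    spatial_threshold_m: float = 30.0
    merge_gap_s: float = 1800.0          # temporal threshold for merging visits
    min_dwell_s: float = 300.0           # minimum dwell for a stay
    fix_cover_max_s: float = 450.0       # a fix covers at most this much time
    # civil-time windows (local hours)
    night_start_hour: int = 0
    night_end_hour: int = 6
    day_start_hour: int = 10
    day_end_hour: int = 18
    prompt_start_hour: int = 9
    prompt_end_hour: int = 21
    # feature building
    max_pair_span_s: float = 14400.0     # prompt pairs farther apart are dropped
    log_epsilon: float = 0.01
    locf_max_s: float = 0.0              # 0 disables the cap
    # models / report
    alpha: float = 0.05
    standardize_outcome: bool = True

    def validate(self) -> "PipelineConfig":
        if self.spatial_threshold_m <= 0 or self.min_dwell_s <= 0:
            raise ConfigError("spatial/dwell thresholds must be positive")
        if self.gps_interval <= 0:
            raise ConfigError("gps_interval must be > 0")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.log_epsilon <= 0:
            raise ConfigError("log_epsilon must be > 0")
        if not (0 <= self.night_start_hour < self.night_end_hour <= 24):
            raise ConfigError("night window hours out of order")
        if not (0 <= self.day_start_hour < self.day_end_hour <= 24):
            raise ConfigError("day window hours out of order")
        return self


_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}
_PIPE_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(path: str | Path | None) -> tuple[SimConfig, PipelineConfig]:
    """Load a flat YAML mapping and split it into the two config objects.

    ``path=None`` returns pure defaults.  Unknown keys are an error so typos
    never silently fall back to defaults.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        loaded = yaml.safe_load(p.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config must be a flat key/value mapping: {p}")
        for key, value in loaded.items():
            if isinstance(value, (dict, list)):
                raise ConfigError(f"config key {key!r} is nested; only flat values allowed")
        raw = dict(loaded)
    unknown = set(raw) - _SIM_FIELDS - _PIPE_FIELDS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    sim = SimConfig(**{k: v for k, v in raw.items() if k in _SIM_FIELDS}).validate()
    pipe_kwargs = {k: v for k, v in raw.items() if k in _PIPE_FIELDS}
    # shared keys follow the simulation unless explicitly overridden
    pipe_kwargs.setdefault("gps_interval", sim.gps_interval)
    pipe_kwargs.setdefault("timezone", sim.timezone)
    pipe = PipelineConfig(**pipe_kwargs).validate()
    return sim, pipe


def dump_config(sim: SimConfig, pipe: PipelineConfig) -> dict[str, Any]:
    """Flatten both configs back into one mapping (for run metadata)."""
    merged = dataclasses.asdict(sim)
    merged.update(dataclasses.asdict(pipe))
    return merged
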