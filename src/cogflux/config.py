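"""Configuration objects for the simulator and the analysis pipeline.

All thresholds that the analysis applies (non-wear step cutoff, sparse-hour
minimum, selection and adequacy alpha levels) live here and only here; stage
code receives them from a :class:`PipelineConfig` rather than hard-coding them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration field violates its documented range."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic high-frequency assessment cohort.

    The defaults describe a 6-week study of 30 outpatients with mild-moderate
    depression wearing a smartwatch: three brief 2-back sessions per day, up to
    two mood prompts per day (the evening prompt suppressed when the afternoon
    one was answered), daily step counts and mean heart rate, practice effects
    on d-prime following an inverse curve ``intercept + a - b/k`` over
    completed assessments ``k``, quadratic time-of-day structure in d-prime,
    a subtle linear drift in mood, quadratic day-of-week structure in steps
    and heart rate, same-day and previous-day coupling of step fluctuations
    to mood, AR(1) serial noise, occasional non-wear days, and prompt/session
    nonresponse.
    """

    # cohort geometry
    n_participants: int = 30
    n_days: int = 42
    sessions_per_day: int = 3
    trials_per_session: int = 30
    n_target_trials: int = 9
    symbol_pool_size: int = 227

    # learning curve (d-prime units / assessment-scaled units)
    intercept_mean: float = 0.95
    intercept_sd: float = 0.55
    asymptote_mean: float = 1.0
    asymptote_sd: float = 0.20
    slope_mean: float = 2.2
    slope_sd: float = 0.5
    fraction_non_learners: float = 0.1

    # quadratic time-of-day effect on d-prime, clock hours centred at 14.5
    diurnal_linear: float = -0.03
    diurnal_quadratic: float = 0.010

    # explicit polynomial day trend added to latent d-prime (day-1 scaled);
    # used by trend-recovery studies, zero under the practice-curve default
    dprime_day_poly: tuple[float, float, float] = (0.0, 0.0, 0.0)

    # mood (summed 3-item score, range 3-12; higher = worse)
    mood_baseline_mean: float = 7.5
    mood_baseline_sd: float = 1.5
    mood_day_trend: float = -0.01

    # daily steps; weekday terms act on the square-root scale, centred weekday
    step_mean: float = 7000.0
    step_sd: float = 2000.0
    step_weekday_linear: float = 0.3
    step_weekday_quadratic: float = -0.8

    # mean daily heart rate; weekday terms act on the log scale
    hr_mean: float = 72.0
    hr_sd: float = 5.0
    hr_weekday_linear: float = 0.002
    hr_weekday_quadratic: float = -0.002

    # cross-domain couplings (fluctuation scale)
    coupling_step_mood_same_day: float = -0.001  # mood points per raw step
    coupling_step_mood_lag1: float = -0.001
    coupling_dprime_mood: float = -0.06  # mood points per d-prime unit
    corr_asymptote_steps: float = 0.0  # Spearman target between a_i and mean steps

    # serial noise
    noise_sd_dprime: float = 0.45
    noise_sd_mood: float = 1.0
    noise_sd_steps: float = 1.2  # sqrt-step scale (~200 raw steps day-to-day)
    noise_sd_hr: float = 0.03  # log-bpm scale
    ar_phi_dprime: float = 0.05  # continuous-time base, per day
    ar_phi_mood: float = 0.3
    ar_phi_steps: float = 0.3
    ar_phi_hr: float = 0.5

    # missingness
    p_nonwear_day: float = 0.02
    p_session_missing: float = 0.10
    p_mood_missing: float = 0.15

    # session clock windows (start hour, end hour), morning/afternoon/evening
    session_windows: tuple[tuple[float, float], ...] = (
        (8.0, 11.0),
        (13.0, 16.0),
        (18.0, 21.0),
    )
    mood_afternoon_window: tuple[float, float] = (13.0, 17.0)
    mood_evening_window: tuple[float, float] = (19.0, 22.0)

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = (
            "n_participants", "n_days", "sessions_per_day",
            "trials_per_session", "n_target_trials", "symbol_pool_size",
        )
        for name in counts:
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be a positive count")
        if self.n_target_trials > self.trials_per_session - 2:
            raise ConfigError(
                "n_target_trials must leave room for the two lead-in trials "
                "(n_target_trials <= trials_per_session - 2)"
            )
        for name in ("fraction_non_learners", "p_nonwear_day",
                     "p_session_missing", "p_mood_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for f in fields(self):
            if f.name.endswith("_sd"):
                if getattr(self, f.name) < 0:
                    raise ConfigError(f"{f.name} must be >= 0")
            if f.name.startswith("ar_phi"):
                v = getattr(self, f.name)
                if not 0.0 <= v < 1.0:
                    raise ConfigError(f"{f.name} must lie in [0, 1), got {v}")
        if self.asymptote_mean <= 0:
            raise ConfigError("asymptote_mean must be positive (a > 0)")
        if self.slope_mean < 0:
            raise ConfigError("slope_mean must be >= 0 (b >= 0)")
        if not -1.0 <= self.corr_asymptote_steps <= 1.0:
            raise ConfigError("corr_asymptote_steps must lie in [-1, 1]")
        if len(self.session_windows) < self.sessions_per_day:
            raise ConfigError("need one session window per daily session")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        return cls(**_load_mapping(path))

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings with the study's published thresholds."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    nonwear_step_threshold: int = 100  # days with fewer steps count as non-wear
    sparse_hour_min: int = 25  # pooled per-hour minimum before an hour is kept
    selection_alpha: float = 0.05  # sequential likelihood-ratio model selection
    adequacy_alpha: float = 0.05  # learning-curve parameter significance
    transforms: dict[str, str] = field(
        default_factory=lambda: {
            "dprime": "identity",
            "mood": "identity",
            "steps": "sqrt",
            "heart_rate": "log",
        }
    )
    smoothing_window: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.nonwear_step_threshold < 0 or self.sparse_hour_min < 0:
            raise ConfigError("thresholds must be non-negative")
        for alpha in (self.selection_alpha, self.adequacy_alpha):
            if not 0 < alpha < 1:
                raise ConfigError("alpha levels must lie in (0, 1)")
        if self.smoothing_window < 1:
            raise ConfigError("smoothing_window must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = _load_mapping(path)
        sim = data.pop("simulation", None)
        cfg = cls(**data) if sim is None else cls(
            simulation=SimulationConfig(**sim), **data
        )
        cfg.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def _load_mapping(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    # YAML loads tuples as lists; normalise nested sequences
    for key, value in data.items():
        if isinstance(value, list):
            data[key] = tuple(
                tuple(v) if isinstance(v, list) else v for v in value
            )
    return data
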