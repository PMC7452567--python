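"""Pipeline configuration.

All tunable thresholds and seeds for a pipeline run live in a single
:class:`PipelineConfig`, loadable from YAML, so that two runs with the same
config file are numerically identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its constraints."""


@dataclass
class CleaningConfig:
    """Trial-discard thresholds for the dot-probe reaction-time data.

    rt_min / rt_max are exclusive absolute bounds in milliseconds (a trial is
    discarded when rt < rt_min or rt > rt_max); sd_multiplier is the
    per-cell outlier criterion (|rt - m| > sd_multiplier * s);
    discard_fraction_limit is the strict per-cell participant-exclusion
    threshold. sd_after_absolute and errors_in_sd_stats expose the two
    conventions for which trials enter the mean/SD of the outlier rule.
    """

    rt_min: float = 200.0
    rt_max: float = 2000.0
    sd_multiplier: float = 2.0
    discard_fraction_limit: float = 0.20
    sd_after_absolute: bool = True
    errors_in_sd_stats: bool = False

    def validate(self) -> None:
        if self.rt_min <= 0 or self.rt_max <= 0:
            raise ConfigError("rt bounds must be positive")
        if self.rt_min >= self.rt_max:
            raise ConfigError(f"rt_min ({self.rt_min}) must be < rt_max ({self.rt_max})")
        if self.sd_multiplier <= 0:
            raise ConfigError("sd_multiplier must be positive")
        if not 0 < self.discard_fraction_limit <= 1:
            raise ConfigError("discard_fraction_limit must be in (0, 1]")


@dataclass
class ReliabilityConfig:
    """Split-half resampling settings.

    correction_order chooses whether the Spearman-Brown prophecy formula is
    applied to the mean of the per-split correlations (average_then_correct)
    or to each split before averaging (correct_then_average).
    """

    n_splits: int = 5000
    seed: int = 0
    correction_order: str = "average_then_correct"
    stratified: bool = True

    def validate(self) -> None:
        if self.n_splits < 1:
            raise ConfigError("n_splits must be >= 1")
        if self.correction_order not in ("average_then_correct", "correct_then_average"):
            raise ConfigError(f"unknown correction_order {self.correction_order!r}")


@dataclass
class ClassificationConfig:
    """Jacobson-Truax thresholds (z multipliers for reliable and clinical change)."""

    rci_multiplier: float = 1.96
    criterion_a_multiplier: float = 1.96
    direction_of_improvement: str = "decrease"

    def validate(self) -> None:
        if self.rci_multiplier <= 0 or self.criterion_a_multiplier <= 0:
            raise ConfigError("classification multipliers must be positive")
        if self.direction_of_improvement not in ("decrease", "increase"):
            raise ConfigError("direction_of_improvement must be 'decrease' or 'increase'")


@dataclass
class ModelConfig:
    """Mixed-model settings.

    method 'ml' keeps AIC and likelihood-ratio comparisons valid across models
    with different fixed effects. pseudo_r2_n picks the observation-count
    convention for the Nagelkerke coefficient. df_method 'containment' splits
    denominator df into between- and within-participant strata; 'residual'
    uses n_obs - n_fixed for every term.
    """

    method: str = "ml"
    pseudo_r2_n: str = "observations"
    df_method: str = "containment"

    def validate(self) -> None:
        if self.method not in ("ml", "reml"):
            raise ConfigError("method must be 'ml' or 'reml'")
        if self.pseudo_r2_n not in ("observations", "participants"):
            raise ConfigError("pseudo_r2_n must be 'observations' or 'participants'")
        if self.df_method not in ("containment", "residual"):
            raise ConfigError("df_method must be 'containment' or 'residual'")


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs; seeds included, so runs reproduce."""

    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    reliability: ReliabilityConfig = field(default_factory=ReliabilityConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    simulate: bool = True
    seed: int = 0
    n_participants: int = 100
    trials_path: str | None = None
    scores_path: str | None = None
    allocations_path: str | None = None
    out_dir: str = "abmtrial_out"

    def validate(self) -> None:
        self.cleaning.validate()
        self.reliability.validate()
        self.classification.validate()
        self.model.validate()
        if not self.simulate:
            for name in ("trials_path", "scores_path", "allocations_path"):
                if getattr(self, name) is None:
                    raise ConfigError(f"simulate=false requires {name}")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config file mirroring :class:`PipelineConfig` and validate it."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    sections = {
        "cleaning": CleaningConfig,
        "reliability": ReliabilityConfig,
        "classification": ClassificationConfig,
        "model": ModelConfig,
    }
    kwargs: dict = {}
    for key, value in raw.items():
        if key in sections:
            try:
                kwargs[key] = sections[key](**(value or {}))
            except TypeError as exc:
                raise ConfigError(f"bad {key} section: {exc}") from exc
        else:
            kwargs[key] = value
    try:
        cfg = PipelineConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    cfg.validate()
    return cfg
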