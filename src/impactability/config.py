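"""Configuration objects for cohort simulation and pipeline runs.

Two dataclasses: :class:`SynthConfig` parameterizes the synthetic-cohort
generator, :class:`RunConfig` carries the analysis constants (prevalence
bounds, correlation cap, SMD flag threshold, risk / benefit cut-points,
bootstrap replications ...) for a full pipeline run.  Both round-trip
through YAML so every run can persist the exact configuration beside its
outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration field is out of its documented range."""


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"invalid config field {name!r}: {msg}")


@dataclass
class SynthConfig:
    """Parameters of the synthetic patient-episode cohort generator.

    The generator emulates the statistical structure of a case-management
    evaluation cohort: a sparse high-dimensional binary covariate block,
    continuous covariates with missingness, confounded program enrollment,
    a monthly outcome panel over months -12..-1 and 1..12 with a
    pre-enrollment trend, a post-enrollment level change for enrollees,
    zero inflation in event-day counts and payments, covariate-driven
    (heterogeneous) treatment benefit, and geometric censoring of
    follow-up.

    Dollar-valued heterogeneity: ``b(x) = benefit_intercept +
    benefit_coefficients . x`` is the expected reduction in monthly
    payments for an enrolled patient, so ``12 * b(x)`` is the per-patient
    1-year benefit on the scale the benefit score targets.
    """

    n_patients: int = 4000
    n_binary_covariates: int = 500
    n_continuous_covariates: int = 20
    missing_rate: float = 0.10
    confounder_indices: Sequence[int] = (0, 1, 2, 3, 4)
    confounder_log_odds: Sequence[float] = (1.0, 1.0, 1.0, 1.0, 1.0)
    outcome_confounder_effects: Sequence[float] = (0.5, 0.5, 0.5, 0.5, 0.5)
    enrollment_rate: float = 0.05
    baseline_event_prob: float = 0.15
    baseline_trend_per_month: float = 0.01
    effect_level: float = -0.35
    benefit_intercept: float = 100.0
    benefit_coefficients: Sequence[float] = (400.0, 250.0, -150.0)
    benefit_event_scale: float = 0.0005
    baseline_payment_mean: float = 3800.0
    zip_zero_prob: float = 0.35
    gamma_shape: float = 1.5
    censor_hazard_per_month: float = 0.03
    max_candidate_episodes: int = 3
    payment_floor: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_patients > 0, "n_patients", "must be positive")
        _check(self.n_binary_covariates > 0, "n_binary_covariates", "must be positive")
        _check(self.n_continuous_covariates >= 0, "n_continuous_covariates", "must be >= 0")
        for name in ("missing_rate", "zip_zero_prob", "censor_hazard_per_month"):
            v = getattr(self, name)
            _check(0.0 <= v < 1.0, name, "must lie in [0, 1)")
        for name in ("enrollment_rate", "baseline_event_prob"):
            v = getattr(self, name)
            _check(0.0 < v < 1.0, name, "must lie in (0, 1)")
        _check(self.gamma_shape > 0, "gamma_shape", "must be positive")
        _check(self.baseline_payment_mean > 0, "baseline_payment_mean", "must be positive")
        _check(self.payment_floor > 0, "payment_floor", "must be positive")
        _check(1 <= self.max_candidate_episodes <= 12, "max_candidate_episodes", "must be in 1..12")
        idx = list(self.confounder_indices)
        _check(all(0 <= i < self.n_binary_covariates for i in idx),
               "confounder_indices", "indices must address binary covariates")
        _check(len(idx) == len(set(idx)), "confounder_indices", "indices must be unique")
        _check(len(self.confounder_log_odds) == len(idx),
               "confounder_log_odds", "length must match confounder_indices")
        _check(len(self.outcome_confounder_effects) == len(idx),
               "outcome_confounder_effects", "length must match confounder_indices")
        _check(len(self.benefit_coefficients) <= self.n_binary_covariates,
               "benefit_coefficients", "cannot exceed number of binary covariates")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_as_plain_dict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class RunConfig:
    """Analysis constants for a full pipeline run.

    Defaults are the constants of the evaluated study design: covariate
    prevalence bounds 5%/95% and correlation cap 0.8 for screening, a
    two-sided 5% significance screen for confounder prioritization, up to
    4 matched comparison episodes per case, an SMD flag threshold of 0.25
    for residual-confounder adjustment, the >13% high-risk cut-point,
    quintile >= 2 (and the operational >$1200) high-benefit rules, and 400
    bootstrap replications.
    """

    synth: SynthConfig = field(default_factory=SynthConfig)
    exact_schedule: Sequence[Sequence[str]] | None = None
    k_max: int = 4
    prevalence_low: float = 0.05
    prevalence_high: float = 0.95
    correlation_cap: float = 0.8
    significance_alpha: float = 0.05
    smd_flag_threshold: float = 0.25
    risk_threshold: float = 0.13
    benefit_high_quintile: int = 2
    benefit_dollar_threshold: float = 1200.0
    bootstrap_replications: int = 400
    match_candidate_cap: int | None = 80
    seed: int = 0

    def __post_init__(self) -> None:
        _check(1 <= self.k_max, "k_max", "must be >= 1")
        _check(0 <= self.prevalence_low < self.prevalence_high <= 1,
               "prevalence_low", "bounds must satisfy 0 <= low < high <= 1")
        _check(0 < self.correlation_cap <= 1, "correlation_cap", "must lie in (0, 1]")
        _check(0 < self.significance_alpha <= 1, "significance_alpha", "must lie in (0, 1]")
        _check(self.bootstrap_replications >= 2, "bootstrap_replications", "must be >= 2")
        if isinstance(self.synth, dict):
            self.synth = SynthConfig(**self.synth)

    @property
    def ci_reliable(self) -> bool:
        # percentile 95% CIs need enough replicates for the tail quantiles
        return self.bootstrap_replications >= 40

    def to_yaml(self, path: str | Path) -> None:
        d = _as_plain_dict(self)
        d["synth"] = _as_plain_dict(self.synth)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _as_plain_dict(obj) -> dict:
    d = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if dataclasses.is_dataclass(v):
            v = _as_plain_dict(v)
        elif isinstance(v, tuple):
            v = list(v)
        d[f.name] = v
    return d
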