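"""Structured run configuration (YAML) with strict schema validation.

One config file drives the whole pipeline: schedule block, parameter
overrides, genotype/condition lists, noise block for the synthetic
generator, and the fitting block.  Unknown keys are rejected so typos
fail loudly with field paths.
"""

from __future__ import annotations

import hashlib
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .fitting import FitSpec
from .params import AntisenseParams, ModelParams, set_param
from .synthetic import DEFAULT_TIMEPOINTS, NoiseModel


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScheduleConfig(_Strict):
    weeks_cold: float = 6.0
    pre_days: float = 14.0
    post_days: float = 28.0
    warm_T: float = 22.0
    shape: str = "square"
    cold_fraction: float = 0.625

    @field_validator("weeks_cold", "pre_days", "post_days")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("durations must be positive")
        return v


class NoiseConfig(_Strict):
    cv: float = 0.25
    n_reps: int = 3


class FitConfig(_Strict):
    free_params: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {"k_nuc0": (0.02, 0.6),
                                 "gamma36": (0.02, 1.0),
                                 "antisense.a_slow_max": (0.2, 0.95)})
    fixed_overrides: dict[str, float] = Field(default_factory=dict)
    loss: str = "linear"
    weights: str = "sem"
    starts: int = 10
    maxiter: int = 80
    init: Optional[dict[str, float]] = None


class RunConfig(_Strict):
    seed: int = 0
    output_dir: str = "flcdyn_out"
    schedule: ScheduleConfig = Field(default_factory=ScheduleConfig)
    params: dict[str, object] = Field(default_factory=dict)
    antisense: dict[str, object] = Field(default_factory=dict)
    genotypes: list[str] = Field(default_factory=lambda: ["wild_type"])
    conditions: list[str] = Field(default_factory=lambda: ["CC"])
    timepoints: list[str] = Field(default_factory=lambda: list(DEFAULT_TIMEPOINTS))
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    log_level: str = "INFO"

    # --- realization ---------------------------------------------------
    def model_params(self) -> ModelParams:
        p = ModelParams()
        a = AntisenseParams()  # dummy sink for misplaced keys -> error below
        for k, v in self.params.items():
            if k.startswith("antisense."):
                raise ValueError(f"params block: move {k!r} to the antisense "
                                 f"block")
            set_param(p, a, k, v)
        p.validate()
        return p

    def antisense_params(self) -> AntisenseParams:
        a = AntisenseParams()
        for k, v in self.antisense.items():
            if not hasattr(a, k):
                raise ValueError(f"antisense block: unknown field {k!r}")
            setattr(a, k, v)
        a.validate()
        return a

    def noise_model(self) -> NoiseModel:
        return NoiseModel(cv=self.noise.cv, n_reps=self.noise.n_reps,
                          seed=self.seed)

    def fitspec(self) -> FitSpec:
        return FitSpec(
            free_params={k: tuple(v) for k, v in self.fit.free_params.items()},
            fixed_overrides=dict(self.fit.fixed_overrides),
            loss=self.fit.loss, weights=self.fit.weights,
            starts=self.fit.starts, seed=self.seed, init=self.fit.init,
            weeks_cold=self.schedule.weeks_cold,
            post_days=self.schedule.post_days, maxiter=self.fit.maxiter)

    def digest(self) -> str:
        """Stable hash of the fully-resolved config, for run logs."""
        canon = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
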