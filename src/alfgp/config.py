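"""Validated pipeline configuration (YAML-backed).

Defaults mirror the reference study conditions: 100 000-point sample pool,
500-point validation set, 1000 random frames on top of the min–max–mean
seed, 0.001 a.u. scrubbing threshold, jitter-level nugget, and the package's
PSO swarm defaults.  Every block validates before any stage runs, and the
whole (defaults included) is echoed into the run manifest.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .active_learning import ALConfig, SCRUB_THRESHOLD
from .pso import PSOConfig

__all__ = ["PipelineConfig", "SystemBlock", "SplitBlock", "InitBlock",
           "ALBlock", "PSOBlock", "KernelBlock", "MultipoleBlock"]


class SystemBlock(BaseModel):
    template: str = "water"
    atom_index: int = 0
    unit: str = "angstrom"
    property_tag: str = "iqa"

    @field_validator("unit")
    @classmethod
    def _unit(cls, v: str) -> str:
        if v not in ("angstrom", "bohr"):
            raise ValueError("unit must be 'angstrom' or 'bohr'")
        return v


class SplitBlock(BaseModel):
    sample_size: int = Field(100_000, ge=1)
    validation_size: int = Field(500, ge=1)


class InitBlock(BaseModel):
    random_extra: int = Field(1000, ge=0)


class ALBlock(BaseModel):
    batch: int = Field(5, ge=0)
    iterations: int = Field(10, ge=0)
    target_rmse: float | None = None
    scrub_threshold: float = Field(SCRUB_THRESHOLD, gt=0)


class PSOBlock(BaseModel):
    swarm_size: int = Field(50, ge=1)
    iterations: int = Field(300, ge=1)
    omega_start: float = 0.9
    omega_end: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    bounds: tuple[float, float] = (-3.0, 3.0)
    stall_iterations: int = 50
    stall_tol: float = 1e-8


class KernelBlock(BaseModel):
    nugget: float = Field(1e-8, ge=1e-12)


class MultipoleBlock(BaseModel):
    l_prime: int = Field(4, ge=0, le=4)
    guard_angstrom: float = Field(1.0, gt=0)


class PipelineConfig(BaseModel):
    system: SystemBlock = Field(default_factory=SystemBlock)
    split: SplitBlock = Field(default_factory=SplitBlock)
    init: InitBlock = Field(default_factory=InitBlock)
    al: ALBlock = Field(default_factory=ALBlock)
    pso: PSOBlock = Field(default_factory=PSOBlock)
    kernel: KernelBlock = Field(default_factory=KernelBlock)
    multipole: MultipoleBlock = Field(default_factory=MultipoleBlock)
    seed: int = 0
    output_dir: str = "alfgp-run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    def pso_config(self) -> PSOConfig:
        return PSOConfig(
            swarm_size=self.pso.swarm_size,
            iterations=self.pso.iterations,
            omega_start=self.pso.omega_start,
            omega_end=self.pso.omega_end,
            c1=self.pso.c1,
            c2=self.pso.c2,
            bounds=tuple(self.pso.bounds),
            seed=self.seed,
            stall_iterations=self.pso.stall_iterations,
            stall_tol=self.pso.stall_tol,
        )

    def al_config(self) -> ALConfig:
        return ALConfig(
            batch=self.al.batch,
            iterations=self.al.iterations,
            random_extra=self.init.random_extra,
            sample_size=self.split.sample_size,
            validation_size=self.split.validation_size,
            scrub_threshold=self.al.scrub_threshold,
            target_rmse=self.al.target_rmse,
            nugget=self.kernel.nugget,
            seed=self.seed,
            pso=self.pso_config(),
        )
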