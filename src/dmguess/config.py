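"""Typed run configuration (YAML) for the workbench CLI.

Defaults follow the reference protocol: BLYP functional, cc-pVDZ basis,
1e-9 Ha energy tolerance, 50-iteration cap, 150 K sampling, and a
9000/800/1000 train/validation/test split. Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class SCFBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    functional: str = "BLYP"
    basis: str = "cc-pvdz"
    solver: str = "diis"
    guess: str = "minao"
    energy_tolerance: float = Field(1e-9, gt=0)
    max_iterations: int = Field(50, ge=1)
    grid_level: str = "medium"

    @field_validator("solver")
    @classmethod
    def _solver(cls, v):
        if v not in ("diis", "sos"):
            raise ValueError(f"solver must be diis or sos, got {v!r}")
        return v


class SamplingBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: str = "perturbation"          # perturbation | md
    n_frames: int = Field(400, ge=1)
    temperature: float = Field(150.0, ge=0)
    seed: int = 0

    @field_validator("mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("perturbation", "md"):
            raise ValueError(f"sampling mode must be perturbation or md, got {v!r}")
        return v


class ModelBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hidden_sizes: list[int] | None = None     # default: per-molecule layout
    learning_rate: float = Field(1e-3, gt=0)
    batch_size: int = Field(64, ge=1)
    max_epochs: int = Field(4000, ge=1)
    patience: int = Field(300, ge=1)
    seed: int = 0
    split: tuple[int, int, int] | None = None  # default derived from n_frames


class BenchmarkBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    guesses: list[str] = ["ml", "minao", "one_electron", "atom", "huckel", "vsap"]
    solvers: list[str] = ["sos", "diis"]
    ensemble_size: int = Field(50, ge=1)
    seed: int = 7


class MDBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: str = "ml"                    # ml | minao_one_step | full_scf
    temperature: float = Field(150.0, ge=0)
    dt_fs: float = Field(0.5, gt=0)
    n_steps: int = Field(200, ge=1)
    thermostat: str | None = "nose-hoover"
    seed: int = 0


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    molecule: str
    workdir: str = "runs"
    scf: SCFBlock = SCFBlock()
    sampling: SamplingBlock = SamplingBlock()
    model: ModelBlock = ModelBlock()
    benchmark: BenchmarkBlock = BenchmarkBlock()
    md: MDBlock = MDBlock()
    engine: str = "real"                # real | mock

    @field_validator("molecule")
    @classmethod
    def _molecule(cls, v):
        if v not in ("h2o", "s2o", "fe_hexaaqua"):
            raise ValueError(f"molecule must be h2o, s2o or fe_hexaaqua, got {v!r}")
        return v

    def scf_config(self):
        from .engine.api import SCFConfig

        return SCFConfig(functional=self.scf.functional, basis=self.scf.basis,
                         solver=self.scf.solver, guess=self.scf.guess,
                         energy_tolerance=self.scf.energy_tolerance,
                         max_iterations=self.scf.max_iterations,
                         grid_level=self.scf.grid_level)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


class ConfigError(ValueError):
    pass


def validate_config(path: str) -> RunConfig:
    """Load + validate a YAML config; errors name the offending key."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    try:
        return RunConfig(**raw)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc
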