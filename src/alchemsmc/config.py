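"""Run configuration: schema-validated YAML blocks.

A run file has four blocks — ``system`` (registry name + parameters),
``move`` (the lambda=0 generator), ``smc`` (engine hyperparameters) and
``output`` — all validated strictly: unknown keys are rejected with a
message naming the offending key, and every omitted field takes the
engine default.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .engine import SMCConfig
from .lambda0 import MOVE_KINDS, Lambda0MoveSpec
from .systems import CouplingProtocol, PotentialSystem, build_system

__all__ = ["RunSetup", "load_config", "dump_config", "normalize_config"]


class SystemBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    params: dict = Field(default_factory=dict)


class MoveBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str = "torsion"
    radius: float = Field(default=1.0, gt=0)
    half_widths: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def to_spec(self) -> Lambda0MoveSpec:
        if self.kind not in MOVE_KINDS:
            raise ValueError(f"unknown move kind '{self.kind}'")
        return Lambda0MoveSpec(
            kind=self.kind, radius=self.radius, half_widths=self.half_widths
        )


class ProtocolBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: str = "split"
    switch_point: float = Field(default=0.8, gt=0, lt=1)


class SMCBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_walkers: int = Field(default=500, ge=1)
    oversample_factor: int = Field(default=100, ge=1)
    overlap_target: float = Field(default=0.5, gt=0, lt=1)
    overlap_metric: str = "r_min"
    decorrelation_threshold: float = Field(default=0.1, gt=0, lt=1)
    bisection_tolerance: float = Field(default=0.01, gt=0)
    max_bisection_iterations: int = Field(default=50, ge=1)
    propagation_block: int = Field(default=100, ge=1)
    max_propagation_blocks: int = Field(default=100, ge=1)
    rng_seed: int = 0
    protocol: ProtocolBlock = Field(default_factory=ProtocolBlock)
    step_sizes: tuple[float, ...] | None = None
    reuse_schedule: tuple[float, ...] | None = None
    skip_resample_when_uniform: bool = False

    def to_config(self, seed: int | None = None) -> SMCConfig:
        data = self.model_dump()
        proto = data.pop("protocol")
        if seed is not None:
            data["rng_seed"] = int(seed)
        return SMCConfig(protocol=CouplingProtocol(**proto), **data)


class OutputBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    archive: str | None = None
    summary_csv: str | None = None


class RunConfigModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    system: SystemBlock
    move: MoveBlock
    smc: SMCBlock = Field(default_factory=SMCBlock)
    output: OutputBlock = Field(default_factory=OutputBlock)


class RunSetup:
    """Fully resolved run configuration: system + move spec + SMC config."""

    def __init__(self, model: RunConfigModel):
        self.model = model
        self.system: PotentialSystem = build_system(
            model.system.name, model.system.params
        )
        self.move_spec: Lambda0MoveSpec = model.move.to_spec()
        # the pair system's coupling protocol lives in the system block;
        # mirror the smc protocol onto the system when both are present
        if hasattr(self.system, "protocol") and "protocol" not in model.system.params:
            self.system.protocol = CouplingProtocol(
                **model.smc.protocol.model_dump()
            )
        self.output = model.output

    def smc_config(self, seed: int | None = None) -> SMCConfig:
        return self.model.smc.to_config(seed=seed)


def _format_error(err: ValidationError) -> ValueError:
    first = err.errors()[0]
    loc = ".".join(str(p) for p in first["loc"]) or "<root>"
    return ValueError(f"config schema violation at '{loc}': {first['msg']}")


def load_config(path) -> RunSetup:
    """Load, validate and fully default a YAML run configuration."""
    with open(Path(path)) as fh:
        raw = yaml.safe_load(fh) or {}
    return load_config_dict(raw)


def load_config_dict(raw: dict) -> RunSetup:
    try:
        model = RunConfigModel.model_validate(raw)
    except ValidationError as err:
        raise _format_error(err) from err
    return RunSetup(model)


def normalize_config(raw: dict) -> dict:
    """The fully defaulted canonical form of a raw config dict."""
    try:
        return RunConfigModel.model_validate(raw).model_dump()
    except ValidationError as err:
        raise _format_error(err) from err


def dump_config(setup: RunSetup) -> dict:
    """Canonical dict form; dump(load(x)) == normalize(x)."""
    return setup.model.model_dump()
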