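"""Run configuration: a YAML-backed, schema-validated description of a run.

Every knob has an explicit default, and the resolved configuration (all
defaults filled in) is written next to the outputs so that a run directory
is self-describing and reproducible from the config plus the seed list.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class LadderConfig(BaseModel):
    values: list[float] = [4.0, 5.0, 6.0, 7.0]
    gradient_mode: bool = False
    pH_in: float | None = 7.2

    @field_validator("values")
    @classmethod
    def _increasing(cls, v: list[float]) -> list[float]:
        if len(v) < 2 or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("ladder must be strictly increasing with >= 2 values")
        return v


class ScheduleConfig(BaseModel):
    n_cycles: int = Field(1000, ge=1)
    n_replicates: int = Field(4, ge=1)
    tau_prot: int = Field(20, ge=1)
    tau_rlx: int = Field(2, ge=0)
    exchange_every: int = Field(1, ge=1)
    mc_cycles_per_update: int = Field(50, ge=1)
    burn_in_fraction: float = Field(0.5, ge=0.0, lt=1.0)


class SurrogateConfig(BaseModel):
    pK_mod: float = 5.5
    dpK_desolv: float = Field(2.0, ge=0.0)
    z_mid: float = 0.0
    z_width: float = Field(2.0, gt=0.0)
    conf_step: float = Field(1.5, gt=0.0)
    well_center: float = 0.0
    well_k: float = Field(0.02, gt=0.0)
    w_partner: float = 0.0


class AnalysisConfig(BaseModel):
    bin_width: float = Field(1.0, gt=0.0)
    burn_in_fraction: float = Field(0.0, ge=0.0, lt=1.0)
    bootstrap: int = Field(1000, ge=1)
    surface_radius: float = Field(6.0, gt=0.0)
    surface_min_atoms: int = Field(10, ge=1)
    bulk_cutoff: float = Field(15.0, gt=0.0)


class RunConfig(BaseModel):
    """Top-level configuration for `phremc phre-run`."""

    propagator: str = "surrogate"  # 'surrogate' or 'frozen'
    energy_terms: str | None = None  # required for the frozen propagator
    bath_file: str | None = None
    ladder: LadderConfig = LadderConfig()
    schedule: ScheduleConfig = ScheduleConfig()
    surrogate: SurrogateConfig = SurrogateConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    pair_threshold: float = Field(2.0, gt=0.0)
    seeds: list[int] | None = None
    base_seed: int = 0
    output_dir: str = "phre_out"

    model_config = {"extra": "forbid"}

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.propagator not in ("surrogate", "frozen"):
            raise ValueError("propagator must be 'surrogate' or 'frozen'")
        if self.propagator == "frozen" and self.energy_terms is None:
            raise ValueError("frozen propagator requires an energy_terms file")
        if self.seeds is not None and len(self.seeds) != self.schedule.n_replicates:
            raise ValueError("seeds must have one entry per replicate")
        return self

    def resolved_seeds(self) -> list[int]:
        if self.seeds is not None:
            return list(self.seeds)
        return [
            (self.base_seed * 100003 + 7919 * k) % (2**31)
            for k in range(self.schedule.n_replicates)
        ]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration (all defaults explicit)."""
    data = cfg.model_dump()
    data["seeds"] = cfg.resolved_seeds()
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
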