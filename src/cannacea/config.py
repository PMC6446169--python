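"""Run configuration: a validated, file-loadable description of one analysis."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .engine import EngineOptions
from .parameters import default_parameter_file

__all__ = ["RunConfig", "load_config"]


class EngineOptionsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    drug_cost_when_nonadherent: bool = True
    cannabis_cost_when_nonadherent: bool = True
    exhausted_policy: Literal["stay_on_last", "no_drug"] = "stay_on_last"
    redraw_responses: bool = False
    nonadherent_cannabis_fail_cycles: int = Field(default=2, ge=1)
    visit_every_cycle: bool = True

    def to_options(self) -> EngineOptions:
        return EngineOptions(**self.model_dump())


class RunConfig(BaseModel):
    """Settings for one model run; unknown keys are rejected.

    The base case is the shipped default: 1-year horizon, 3% annual
    discounting (carried in the parameter file), point-estimate parameters.
    """

    model_config = ConfigDict(extra="forbid")

    parameter_file: Path | None = None
    mode: Literal["base", "tornado", "psa", "scenario"] = "base"
    n_patients: int = Field(default=100_000, ge=1)
    n_iterations: int = Field(default=10_000, ge=1)
    horizon_years: float = Field(default=1.0, gt=0)
    seed: int | None = None
    output_dir: Path | None = None
    scenario: str | None = None
    wtp_grid: list[float] = Field(
        default_factory=lambda: [float(w) for w in range(0, 200_001, 5_000)])
    overwrite: bool = False
    engine: EngineOptionsConfig = Field(default_factory=EngineOptionsConfig)

    @field_validator("wtp_grid")
    @classmethod
    def _wtp_nonnegative_ascending(cls, grid: list[float]) -> list[float]:
        if not grid or any(w < 0 for w in grid) or sorted(grid) != grid:
            raise ValueError("wtp_grid must be nonempty, nonnegative and ascending")
        return grid

    @model_validator(mode="after")
    def _check_stochastic_modes(self) -> "RunConfig":
        if self.seed is None:
            raise ValueError("seed is required for every stochastic run mode")
        if self.mode == "scenario" and self.scenario is None:
            raise ValueError("scenario mode requires a scenario name")
        return self

    def resolved_parameter_file(self) -> Path:
        return self.parameter_file if self.parameter_file is not None else default_parameter_file()

    def engine_options(self) -> EngineOptions:
        return self.engine.to_options()


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Validation errors report the offending field paths (pydantic
    messages); unknown keys are rejected.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    with open(p, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
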