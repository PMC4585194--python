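"""Run configuration, validation, and output serialization.

A run is described either by a named scenario from the library or by an
explicit (subsystem, initial state, alpha, horizon) tuple, plus optional
parameter overrides and solver settings.  Configuration files are flat
JSON or YAML; unknown keys are rejected with the offending name.  Outputs
are a trajectory CSV (columns ``t,I,D,D_G,A,T_P,T_A,G``; the graft-function
column is present only when a graft is), report JSON files, and a run log
recording the fully resolved parameter set, so identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .dynamics import Trajectory
from .params import ModelParameters, ParameterError
from .scenarios import SCENARIOS, ScenarioSpec
from .subsystems import SUBSYSTEM_VARS

__all__ = ["RunConfig", "SolverSettings", "ConfigError", "load_config", "write_outputs"]

log = logging.getLogger("graftdyn")


class ConfigError(ValueError):
    """Invalid run configuration."""


class SolverSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    reltol: float = Field(1e-9, gt=0)
    abstol: float = Field(1e-12, gt=0)
    max_step: Optional[float] = Field(None, gt=0)
    method: str = "LSODA"
    grid_dt: float = Field(1.0, gt=0)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    scenario: Optional[str] = None
    subsystem: Literal["full", "dtotal_i", "i_tp", "dg_tp", "dg_tp_i"] = "full"
    initial_state: Optional[list[float]] = None
    alpha: float = Field(0.0, ge=0.0, le=1.0)
    graft_present: bool = True
    horizon: float = Field(10_000.0, gt=0)
    parameters: dict[str, float] = Field(default_factory=dict)
    solver: SolverSettings = Field(default_factory=SolverSettings)
    output_dir: str = "."
    output_formats: list[Literal["csv", "json"]] = Field(default_factory=lambda: ["csv", "json"])

    @field_validator("initial_state")
    @classmethod
    def _nonnegative(cls, v):
        if v is not None and any(x < 0 for x in v):
            raise ValueError("initial_state components must be nonnegative")
        return v

    @field_validator("parameters")
    @classmethod
    def _known_parameters(cls, v):
        try:
            ModelParameters.from_mapping(v)
        except ParameterError as err:
            raise ValueError(str(err)) from err
        return v

    @field_validator("scenario")
    @classmethod
    def _known_scenario(cls, v):
        if v is not None and v not in SCENARIOS:
            raise ValueError(f"unknown scenario {v!r}; see list-scenarios")
        return v

    def resolve(self) -> tuple[ScenarioSpec, ModelParameters]:
        """Turn the config into a concrete scenario and parameter set."""
        params = ModelParameters.from_mapping(self.parameters).replace(alpha=self.alpha)
        if self.scenario is not None:
            spec = SCENARIOS[self.scenario].with_(
                alpha=self.alpha, horizon=self.horizon,
                parameter_overrides=dict(self.parameters),
            )
            return spec, params.replace(alpha=spec.alpha)
        if self.initial_state is None:
            initial = [0.0] * len(SUBSYSTEM_VARS[self.subsystem])
            if self.subsystem == "full":
                initial[3] = params.baseline_a
        else:
            initial = list(self.initial_state)
        spec = ScenarioSpec(
            id="custom",
            initial_state=tuple(initial),
            subsystem=self.subsystem,
            alpha=self.alpha,
            graft_present=self.graft_present,
            horizon=self.horizon,
            parameter_overrides=dict(self.parameters),
        )
        return spec, params


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as err:
        raise ConfigError(f"{path}: parse error: {err}") from err
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    try:
        return RunConfig(**data)
    except ValidationError as err:
        details = "; ".join(
            f"{'.'.join(str(p) for p in e['loc']) or '<root>'}: {e['msg']}" for e in err.errors()
        )
        raise ConfigError(f"{path}: invalid configuration: {details}") from err


def write_outputs(
    traj: Trajectory,
    reports: dict[str, dict],
    config: RunConfig,
    outdir: str | Path | None = None,
    stem: str = "run",
) -> list[Path]:
    """Write trajectory CSV, report JSONs, and the resolved-parameter run log."""
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if "csv" in config.output_formats:
        csv_path = outdir / f"{stem}_trajectory.csv"
        traj.to_frame().to_csv(csv_path, index=False, float_format="%.10g")
        written.append(csv_path)

    if "json" in config.output_formats:
        for name, payload in reports.items():
            json_path = outdir / f"{stem}_{name}.json"
            json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
            written.append(json_path)

    _, params = config.resolve()
    log_path = outdir / f"{stem}_run.log"
    log_lines = [
        f"scenario: {config.scenario or 'custom'}",
        f"subsystem: {config.subsystem if config.scenario is None else SCENARIOS[config.scenario].subsystem}",
        f"alpha: {config.alpha}",
        f"horizon_h: {config.horizon}",
        f"n_report_points: {traj.t.size}",
        f"solver: {traj.metadata.get('solver')}",
        "resolved_parameters:",
    ]
    log_lines += [f"  {k}: {v}" for k, v in sorted(params.to_dict().items())]
    log_path.write_text("\n".join(log_lines) + "\n")
    written.append(log_path)
    for path in written:
        log.info("wrote %s", path)
    return written
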