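"""Run configuration: schema, validation, and loading.

A run is described by one YAML file pointing at the four inputs (evidence
CSV, forecast-store directory, parameter YAML, policy-schedule CSV) plus
the analysis switches.  Validation collects every problem before raising,
so a bad file reports all its defects at once.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pydantic
import yaml

from .core import ConfigError
from .timeline import SCENARIOS, AnalysisConfig

__all__ = ["RunConfig", "load_and_validate"]


class VOIBlock(pydantic.BaseModel):
    """Value-of-information knobs."""

    alloc_p: float = pydantic.Field(0.5, gt=0.0, lt=1.0)
    n_grid_step: int = pydantic.Field(50, ge=1)
    metamodel_degree: int = pydantic.Field(3, ge=1, le=10)
    c_fixed: float = pydantic.Field(2_000_000.0, ge=0.0)
    c_var: float = pydantic.Field(12_000.0, ge=0.0)
    n_max_feasible: int = pydantic.Field(2_500, ge=0)
    n_cap: int = pydantic.Field(10_000, ge=0)


class RunConfig(pydantic.BaseModel):
    """Validated run description."""

    evidence: Path
    forecast_store: Path
    params: Path
    policy_schedule: Path
    out_dir: Path = Path("results")
    wtp: float = pydantic.Field(100_000.0, gt=0.0)
    window_months: float = pydantic.Field(2.0, gt=0.0)
    n_iter: int = pydantic.Field(10_000, ge=1)
    master_seed: int = 20240603
    scenario: str | None = None
    hartung_knapp: bool = True
    extend_forecast: bool = True
    voi: VOIBlock = VOIBlock()

    @pydantic.field_validator("scenario")
    @classmethod
    def _known_scenario(cls, v: str | None) -> str | None:
        if v is not None and v not in SCENARIOS:
            raise ValueError(f"unknown scenario {v!r}; valid: {sorted(SCENARIOS)}")
        return v

    def analysis_config(self) -> AnalysisConfig:
        from .timeline import scenario as apply_scenario

        cfg = AnalysisConfig(
            wtp=self.wtp,
            window_months=self.window_months,
            hartung_knapp=self.hartung_knapp,
            extend_forecast=self.extend_forecast,
            n_iter=self.n_iter,
            master_seed=self.master_seed,
            alloc_p=self.voi.alloc_p,
            n_grid_step=self.voi.n_grid_step,
            metamodel_degree=self.voi.metamodel_degree,
            c_fixed=self.voi.c_fixed,
            c_var=self.voi.c_var,
            n_max_feasible=self.voi.n_max_feasible,
            n_cap=self.voi.n_cap,
        )
        if self.scenario:
            cfg = apply_scenario(cfg, self.scenario)
        return cfg


def load_and_validate(path: str | Path) -> RunConfig:
    """Load a YAML run config, resolving relative paths against the file
    and reporting every validation failure in one error."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"config {path} is not a mapping")
    try:
        cfg = RunConfig(**doc)
    except pydantic.ValidationError as exc:
        problems = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: {problems}") from exc

    resolved = {}
    errors = []
    for field in ("evidence", "forecast_store", "params", "policy_schedule"):
        p = getattr(cfg, field)
        if not p.is_absolute():
            p = path.parent / p
        if not p.exists():
            errors.append(f"{field}: path {p} does not exist")
        resolved[field] = p
    if errors:
        raise ConfigError(f"invalid config {path}: " + "; ".join(errors))
    return cfg.model_copy(update=resolved)
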