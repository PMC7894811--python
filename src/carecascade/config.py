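"""Declarative model configuration: the YAML dialect and its validation.

A configuration replaces the spreadsheet a practitioner would otherwise
maintain: one population block, one ordered list of step definitions, and a
set of named scenarios expressed as *sparse overrides* of the designated
baseline. Writing only what an intervention changes (a proportion, a unit
cost) mirrors the usual "no change to baseline" idiom and prevents
transcription drift between scenario columns.

Schema (``schema_version: 1``)::

    schema_version: 1
    population: {size: <positive number>, label: <text>}
    steps:
      - label: <unique id>
        description: <text>
        proportion: <0..1>
        unit_cost: <>= 0, default 0>
        cost_basis: post_step | pre_step
    scenarios:
      <name>:
        baseline: true        # on exactly one scenario
        description: <text>
        overrides:
          <step label>: {proportion: ..., unit_cost: ..., cost_basis: ...}
    bounds:                   # optional interval analyses
      - scenario: <name>
        intervals:
          - {step: <label>, parameter: proportion|unit_cost|population,
             lower: ..., upper: ..., apply_to: scenario|baseline|both}
    report:
      currency_label: AUD
      rounding: true
      format: table | csv | jsonl
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .cascade import CostBasis, ScenarioSpec, StepSpec
from .uncertainty import IntervalSpec

__all__ = [
    "ConfigError",
    "StepConfig",
    "StepOverride",
    "ScenarioConfig",
    "BoundsConfig",
    "ModelConfig",
    "load_config",
    "write_config",
]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Raised for unparseable or schema-invalid configuration files."""


class PopulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    size: float = Field(gt=0.0)
    label: str = ""


class StepConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    label: str = Field(min_length=1)
    description: str = ""
    proportion: float = Field(ge=0.0, le=1.0)
    unit_cost: float = Field(default=0.0, ge=0.0)
    cost_basis: CostBasis = CostBasis.post_step


class StepOverride(BaseModel):
    """Sparse per-step changes a scenario makes relative to the baseline."""

    model_config = ConfigDict(extra="forbid")

    proportion: float | None = Field(default=None, ge=0.0, le=1.0)
    unit_cost: float | None = Field(default=None, ge=0.0)
    cost_basis: CostBasis | None = None


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    baseline: bool = False
    description: str = ""
    overrides: dict[str, StepOverride] = Field(default_factory=dict)


class BoundsConfig(BaseModel):
    """One interval analysis: a scenario name plus its parameter intervals."""

    model_config = ConfigDict(extra="forbid")

    scenario: str
    intervals: list[IntervalSpec] = Field(min_length=1)


class ReportOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    currency_label: str = "AUD"
    rounding: bool = True
    format: str = "table"


class ModelConfig(BaseModel):
    """A fully validated model configuration."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = SCHEMA_VERSION
    population: PopulationConfig
    steps: list[StepConfig] = Field(min_length=1)
    scenarios: dict[str, ScenarioConfig] = Field(min_length=1)
    bounds: list[BoundsConfig] = Field(default_factory=list)
    report: ReportOptions = Field(default_factory=ReportOptions)

    @model_validator(mode="after")
    def _cross_checks(self) -> "ModelConfig":
        labels = [s.label for s in self.steps]
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        if dupes:
            raise ValueError(f"duplicate step labels: {dupes}")
        baselines = [name for name, sc in self.scenarios.items() if sc.baseline]
        if len(baselines) != 1:
            raise ValueError(
                f"exactly one scenario must set baseline: true, found "
                f"{baselines or 'none'}"
            )
        known = set(labels)
        for name, sc in self.scenarios.items():
            unknown = sorted(set(sc.overrides) - known)
            if unknown:
                raise ValueError(
                    f"scenario {name!r} overrides undefined steps: {unknown}"
                )
        for i, b in enumerate(self.bounds):
            if b.scenario not in self.scenarios:
                raise ValueError(
                    f"bounds[{i}] references unknown scenario {b.scenario!r}"
                )
            for iv in b.intervals:
                if iv.step is not None and iv.step not in known:
                    raise ValueError(
                        f"bounds[{i}] interval targets undefined step {iv.step!r}"
                    )
        return self

    @property
    def baseline_label(self) -> str:
        return next(n for n, sc in self.scenarios.items() if sc.baseline)

    def scenario_spec(self, name: str) -> ScenarioSpec:
        """Materialise one named scenario as a concrete ScenarioSpec."""
        sc = self.scenarios[name]
        steps = []
        for step in self.steps:
            ov = sc.overrides.get(step.label)
            kwargs: dict[str, Any] = dict(
                label=step.label,
                description=step.description,
                proportion=step.proportion,
                unit_cost=step.unit_cost,
                cost_basis=step.cost_basis,
                is_intervention=ov is not None,
            )
            if ov is not None:
                for f in ("proportion", "unit_cost", "cost_basis"):
                    v = getattr(ov, f)
                    if v is not None:
                        kwargs[f] = v
            steps.append(StepSpec(**kwargs))
        return ScenarioSpec(
            label=name,
            population=self.population.size,
            steps=tuple(steps),
            currency_label=self.report.currency_label,
        )

    def scenario_specs(self) -> dict[str, ScenarioSpec]:
        """All scenarios in declaration order, baseline included."""
        return {name: self.scenario_spec(name) for name in self.scenarios}


def _format_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"  {loc}: {err['msg']}")
    return "\n".join(lines)


def load_config(path: str | Path) -> ModelConfig:
    """Read and validate a YAML model configuration.

    Raises
    ------
    ConfigError
        With the offending field paths for any parse or schema failure.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return ModelConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(
            f"invalid configuration {path}:\n{_format_validation_error(exc)}"
        ) from exc


def write_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration back to YAML; round-trips through load_config."""
    payload = config.model_dump(mode="json", exclude_none=True)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
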