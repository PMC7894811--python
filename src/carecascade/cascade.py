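"""Deterministic evaluation of a filter cascade.

A *filter cascade* pushes a starting population through an ordered sequence
of proportion filters (e.g. prevalence of the condition, attendance at the
care setting, detection, offer of treatment, adherence, treatment success).
Each step passes a fixed fraction of its entrants on to the next step, and
may attach a per-person intervention cost. This is a cohort-expectation
model: counts are continuous expected values, never rounded internally.
Rounding to whole persons or whole currency units happens only when a
report is rendered (see :func:`carecascade.economics.round_for_report`).

Steps are assumed to operate independently: changing one step's proportion
never alters another step's proportion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = [
    "CostBasis",
    "StepSpec",
    "ScenarioSpec",
    "StepResult",
    "CascadeResult",
    "apply_step",
    "evaluate_cascade",
]


class CostBasis(str, enum.Enum):
    """Which person-count a step's unit cost multiplies.

    ``post_step``
        Cost applies to the persons remaining *after* the filter (the
        convention used by the bundled worked example: a $5 screening cost
        applied to the detected, not to everyone screened).
    ``pre_step``
        Cost applies to every person *entering* the step (e.g. a screening
        instrument administered to all attendees regardless of result).
    """

    post_step = "post_step"
    pre_step = "pre_step"


class StepSpec(BaseModel):
    """One filter of the cascade.

    Parameters
    ----------
    label
        Short unique identifier within a scenario (e.g. ``"detection"``).
    description
        Free-text explanation of what the filter represents.
    proportion
        Fraction of entrants passing this filter, in [0, 1].
    unit_cost
        Non-negative per-person intervention cost attached to this step
        (0 for an uncosted step).
    cost_basis
        Which count the unit cost multiplies; default ``post_step``.
    is_intervention
        Marks the step an intervention scenario modifies. Reporting only;
        has no effect on the arithmetic.
    """

    model_config = ConfigDict(frozen=True)

    label: str = Field(min_length=1)
    description: str = ""
    proportion: float = Field(ge=0.0, le=1.0)
    unit_cost: float = Field(default=0.0, ge=0.0)
    cost_basis: CostBasis = CostBasis.post_step
    is_intervention: bool = False


class ScenarioSpec(BaseModel):
    """A population plus an ordered sequence of filters."""

    model_config = ConfigDict(frozen=True)

    label: str = Field(min_length=1)
    population: float = Field(gt=0.0)
    steps: tuple[StepSpec, ...] = Field(min_length=1)
    currency_label: str = "AUD"

    @field_validator("steps")
    @classmethod
    def _unique_labels(cls, steps: tuple[StepSpec, ...]) -> tuple[StepSpec, ...]:
        labels = [s.label for s in steps]
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        if dupes:
            raise ValueError(f"duplicate step labels within scenario: {dupes}")
        return steps

    def step(self, label: str) -> StepSpec:
        """Return the step with the given label."""
        for s in self.steps:
            if s.label == label:
                return s
        raise KeyError(f"no step labelled {label!r}")


@dataclass(frozen=True)
class StepResult:
    """Expected counts and cost for one evaluated step (unrounded)."""

    label: str
    entering: float
    proportion: float
    resulting: float
    unit_cost: float
    cost_basis: CostBasis
    step_cost: float

    @property
    def costed_count(self) -> float:
        """The count the unit cost multiplied (cost-basis denominator)."""
        if self.cost_basis is CostBasis.post_step:
            return self.resulting
        return self.entering


@dataclass(frozen=True)
class CascadeResult:
    """Full-precision evaluation of one scenario.

    ``successes`` is the expected count leaving the final step, which by
    construction equals ``population × Π proportions``. ``cost_per_exposed``
    and ``cost_per_success`` are ``None`` when undefined (nonzero cost over
    a zero denominator).
    """

    scenario_label: str
    population: float
    currency_label: str
    step_results: tuple[StepResult, ...]
    successes: float
    total_cost: float
    cost_per_exposed: float | None
    cost_per_success: float | None


def apply_step(entering: float, step: StepSpec) -> StepResult:
    """Pass an expected count of persons through one filter.

    Raises
    ------
    ValueError
        If ``entering`` is negative.
    """
    if entering < 0:
        raise ValueError(f"entering count must be non-negative, got {entering}")
    resulting = entering * step.proportion
    costed = resulting if step.cost_basis is CostBasis.post_step else entering
    return StepResult(
        label=step.label,
        entering=entering,
        proportion=step.proportion,
        resulting=resulting,
        unit_cost=step.unit_cost,
        cost_basis=step.cost_basis,
        step_cost=step.unit_cost * costed,
    )


def evaluate_cascade(scenario: ScenarioSpec) -> CascadeResult:
    """Evaluate every step of a scenario in order.

    The resulting count of step *i* is the entering count of step *i + 1*;
    full floating-point precision is carried throughout.
    """
    # circular at module level: economics consumes CascadeResult
    from . import economics

    results: list[StepResult] = []
    count = scenario.population
    for step in scenario.steps:
        res = apply_step(count, step)
        results.append(res)
        count = res.resulting

    partial = CascadeResult(
        scenario_label=scenario.label,
        population=scenario.population,
        currency_label=scenario.currency_label,
        step_results=tuple(results),
        successes=count,
        total_cost=sum(r.step_cost for r in results),
        cost_per_exposed=None,
        cost_per_success=None,
    )
    return CascadeResult(
        scenario_label=partial.scenario_label,
        population=partial.population,
        currency_label=partial.currency_label,
        step_results=partial.step_results,
        successes=partial.successes,
        total_cost=partial.total_cost,
        cost_per_exposed=economics.cost_per_exposed(partial),
        cost_per_success=economics.cost_per_success(partial),
    )
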