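"""Deterministic sensitivity analysis: parameter ranges to output envelopes.

Instead of point estimates, the user may supply an interval for any input
parameter (a step's passing proportion or unit cost, or the population
size). The module propagates the resulting parameter box to lower/upper
envelopes on every model output.

Counts and total cost are multilinear in the parameters and monotone in
each one, so their exact extrema sit at corners of the box and corner
enumeration suffices. Ratio outputs (cost per success, ICER) are ratios of
multilinear functions, for which corners are *not* guaranteed extremal; the
module therefore additionally evaluates a seeded quasi-random sample of the
box interior and widens the envelope to cover every sampled point. Such
envelopes are labelled ``corner+sampled``. When the incremental success
count changes sign inside the box the ICER is unbounded and its envelope is
reported as undefined with a diagnostic rather than as a misleading pair of
finite numbers.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.stats import qmc

from .cascade import CascadeResult, ScenarioSpec, evaluate_cascade
from .economics import ComparisonResult, compare

__all__ = [
    "ParamField",
    "ApplyTo",
    "IntervalSpec",
    "Envelope",
    "BoundsResult",
    "bounds_joint",
    "bounds_one_way",
]

#: Corner enumeration is 2^k; beyond this many intervals the caller is told
#: to fall back to one-way analysis instead of silently grinding.
DEFAULT_CORNER_LIMIT = 12
DEFAULT_N_SAMPLES = 1000


class ParamField(str, enum.Enum):
    proportion = "proportion"
    unit_cost = "unit_cost"
    population = "population"


class ApplyTo(str, enum.Enum):
    """Which side of the comparison an interval perturbs.

    ``scenario`` (default) varies only the intervention scenario;
    ``baseline`` only the comparator; ``both`` moves the parameter in
    lockstep on both sides — the natural choice for shared inputs such as
    the population size or a proportion the intervention does not touch.
    """

    scenario = "scenario"
    baseline = "baseline"
    both = "both"


class IntervalSpec(BaseModel):
    """A closed range for one scenario parameter.

    ``step`` is the label of the step whose ``proportion`` or ``unit_cost``
    varies; it must be ``None`` when (and only when) the target is the
    population size.
    """

    model_config = ConfigDict(frozen=True)

    step: str | None = None
    parameter: ParamField
    lower: float
    upper: float
    apply_to: ApplyTo = ApplyTo.scenario

    @model_validator(mode="after")
    def _check(self) -> "IntervalSpec":
        if self.lower > self.upper:
            raise ValueError(f"lower {self.lower} exceeds upper {self.upper}")
        if self.parameter is ParamField.proportion:
            if not (0.0 <= self.lower and self.upper <= 1.0):
                raise ValueError(
                    f"proportion interval [{self.lower}, {self.upper}] "
                    "must lie within [0, 1]"
                )
        if self.parameter is ParamField.population:
            if self.step is not None:
                raise ValueError("population interval must not name a step")
            if self.lower <= 0:
                raise ValueError("population must stay positive")
        elif self.step is None:
            raise ValueError(f"interval on {self.parameter.value} must name a step")
        if self.parameter is ParamField.unit_cost and self.lower < 0:
            raise ValueError("unit costs must stay non-negative")
        return self


@dataclass(frozen=True)
class Envelope:
    """Lower/upper bound on one output; ``None`` endpoints mean undefined."""

    lower: float | None
    upper: float | None
    note: str = ""

    @property
    def defined(self) -> bool:
        return self.lower is not None and self.upper is not None


@dataclass(frozen=True)
class BoundsResult:
    """Output envelopes induced by a parameter box.

    ``method`` records how each envelope was obtained: ``corner`` alone is
    exact for the multilinear outputs; ``corner+sampled`` means interior
    sampling widened (or confirmed) the ratio envelopes.
    """

    scenario_label: str
    baseline_label: str
    intervals: tuple[IntervalSpec, ...]
    method: str
    n_corners: int
    n_samples: int
    seed: int
    successes: Envelope = field(default=Envelope(None, None))
    total_cost: Envelope = field(default=Envelope(None, None))
    cost_per_success: Envelope = field(default=Envelope(None, None))
    incremental_cost: Envelope = field(default=Envelope(None, None))
    incremental_successes: Envelope = field(default=Envelope(None, None))
    icer: Envelope = field(default=Envelope(None, None))

    def outputs(self) -> dict[str, Envelope]:
        return {
            "successes": self.successes,
            "total_cost": self.total_cost,
            "cost_per_success": self.cost_per_success,
            "incremental_cost": self.incremental_cost,
            "incremental_successes": self.incremental_successes,
            "icer": self.icer,
        }


def _interval_key(iv: IntervalSpec) -> tuple[str | None, str]:
    return (iv.step, iv.parameter.value)


def _apply_point(
    scenario: ScenarioSpec, intervals: tuple[IntervalSpec, ...], point: np.ndarray, side: ApplyTo
) -> ScenarioSpec:
    """Return a copy of ``scenario`` with the point's parameter values set."""
    updates: dict[tuple[str | None, str], float] = {}
    for iv, value in zip(intervals, point):
        if iv.apply_to is ApplyTo.both or iv.apply_to is side:
            updates[_interval_key(iv)] = float(value)
    if not updates:
        return scenario
    population = updates.pop((None, "population"), scenario.population)
    steps = []
    for step in scenario.steps:
        changes = {
            f: v for (lbl, f), v in updates.items() if lbl == step.label
        }
        steps.append(step.model_copy(update=changes) if changes else step)
    return scenario.model_copy(update={"population": population, "steps": tuple(steps)})


def _validate_intervals(
    scenario: ScenarioSpec, baseline: ScenarioSpec, intervals: tuple[IntervalSpec, ...]
) -> None:
    seen: set[tuple[str, str | None, str]] = set()
    for iv in intervals:
        sides = (
            ("scenario", "baseline")
            if iv.apply_to is ApplyTo.both
            else (iv.apply_to.value,)
        )
        for side in sides:
            key = (side, iv.step, iv.parameter.value)
            if key in seen:
                raise ValueError(
                    f"more than one interval targets {iv.parameter.value} of "
                    f"step {iv.step!r} on the {side} side"
                )
            seen.add(key)
        if iv.step is not None:
            targets = []
            if iv.apply_to in (ApplyTo.scenario, ApplyTo.both):
                targets.append(scenario)
            if iv.apply_to in (ApplyTo.baseline, ApplyTo.both):
                targets.append(baseline)
            for spec in targets:
                if all(s.label != iv.step for s in spec.steps):
                    raise ValueError(
                        f"interval targets step {iv.step!r}, which does not "
                        f"exist in scenario {spec.label!r}"
                    )


def _evaluate_point(
    scenario: ScenarioSpec,
    baseline: ScenarioSpec,
    intervals: tuple[IntervalSpec, ...],
    point: np.ndarray,
) -> tuple[CascadeResult, ComparisonResult]:
    sc = _apply_point(scenario, intervals, point, ApplyTo.scenario)
    bl = _apply_point(baseline, intervals, point, ApplyTo.baseline)
    sc_res = evaluate_cascade(sc)
    return sc_res, compare(sc_res, evaluate_cascade(bl))


def bounds_joint(
    scenario: ScenarioSpec,
    baseline: ScenarioSpec,
    intervals: list[IntervalSpec] | tuple[IntervalSpec, ...],
    *,
    n_samples: int = DEFAULT_N_SAMPLES,
    corner_limit: int = DEFAULT_CORNER_LIMIT,
    seed: int = 0,
) -> BoundsResult:
    """Propagate a joint parameter box to envelopes on every output.

    All intervals vary simultaneously: the reported envelope covers every
    corner of the box plus ``n_samples`` seeded quasi-random (Halton)
    interior points. With every interval degenerate the result collapses
    to the point evaluation.

    Raises
    ------
    ValueError
        If an interval targets a nonexistent parameter, two intervals
        target the same parameter, or more than ``corner_limit`` intervals
        are supplied (2^k corner explosion — use :func:`bounds_one_way`
        per parameter instead).
    """
    intervals = tuple(intervals)
    if not intervals:
        raise ValueError("at least one interval is required")
    _validate_intervals(scenario, baseline, intervals)
    k = len(intervals)
    if k > corner_limit:
        raise ValueError(
            f"{k} intervals imply 2^{k} corner evaluations (limit {corner_limit}); "
            "raise corner_limit or run bounds_one_way per parameter"
        )

    lo = np.array([iv.lower for iv in intervals])
    hi = np.array([iv.upper for iv in intervals])
    corners = np.array(list(itertools.product(*zip(lo, hi))))
    if n_samples > 0:
        sampler = qmc.Halton(d=k, seed=seed)
        samples = lo + sampler.random(n_samples) * (hi - lo)
        points = np.vstack([corners, samples])
    else:
        points = corners

    per_output: dict[str, list[float]] = {name: [] for name in (
        "successes", "total_cost", "cost_per_success",
        "incremental_cost", "incremental_successes", "icer",
    )}
    undefined: set[str] = set()
    for point in points:
        sc_res, cmp_res = _evaluate_point(scenario, baseline, intervals, point)
        values = {
            "successes": sc_res.successes,
            "total_cost": sc_res.total_cost,
            "cost_per_success": sc_res.cost_per_success,
            "incremental_cost": cmp_res.incremental_cost,
            "incremental_successes": cmp_res.incremental_successes,
            "icer": cmp_res.icer,
        }
        for name, value in values.items():
            if value is None:
                undefined.add(name)
            else:
                per_output[name].append(value)

    def envelope(name: str, note: str = "") -> Envelope:
        vals = per_output[name]
        if name in undefined or not vals:
            return Envelope(None, None, note or "undefined at one or more box points")
        return Envelope(min(vals), max(vals), note)

    # Δsuccesses crossing zero makes the ICER unbounded inside the box
    d_succ = per_output["incremental_successes"]
    icer_env: Envelope
    if "icer" in undefined or (d_succ and min(d_succ) <= 0.0 <= max(d_succ)):
        icer_env = Envelope(
            None,
            None,
            "incremental successes cross zero inside the box; "
            "the ICER is unbounded and no finite envelope exists",
        )
    else:
        icer_env = envelope("icer")

    return BoundsResult(
        scenario_label=scenario.label,
        baseline_label=baseline.label,
        intervals=intervals,
        method="corner+sampled" if n_samples > 0 else "corner",
        n_corners=len(corners),
        n_samples=int(n_samples),
        seed=seed,
        successes=envelope("successes"),
        total_cost=envelope("total_cost"),
        cost_per_success=envelope("cost_per_success"),
        incremental_cost=envelope("incremental_cost"),
        incremental_successes=envelope("incremental_successes"),
        icer=icer_env,
    )


def bounds_one_way(
    scenario: ScenarioSpec,
    baseline: ScenarioSpec,
    interval: IntervalSpec,
    **kwargs,
) -> BoundsResult:
    """One-way sensitivity: vary a single parameter, all others fixed.

    Equivalent to :func:`bounds_joint` with one interval; useful for
    tornado-style per-parameter reporting.
    """
    return bounds_joint(scenario, baseline, (interval,), **kwargs)
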