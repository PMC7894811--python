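"""Model execution and report rendering (table, CSV, JSON-lines).

Rendered numbers are exactly ``round_for_report`` of the in-memory
full-precision values — no intermediate rounding, so a re-parsed CSV cell
equals the report-rounded in-memory result. Undefined quantities render
as ``n/a`` (CSV/table) or ``null`` (JSON-lines).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import pandas as pd

from .cascade import CascadeResult, evaluate_cascade
from .config import ModelConfig
from .economics import ComparisonResult, compare, round_for_report
from .uncertainty import BoundsResult, bounds_joint

__all__ = ["ModelReport", "run_model", "run_bounds", "render_report", "FORMATS"]

FORMATS = ("table", "csv", "jsonl")

NA = "n/a"

#: Outcome-block metrics in presentation order.
OUTCOME_METRICS = (
    "cost_per_exposed",
    "cost_per_success",
    "incremental_cost",
    "incremental_successes",
    "icer",
    "policy_advice",
)


@dataclass(frozen=True)
class ModelReport:
    """Everything one model run produced, at full precision."""

    baseline_label: str
    currency_label: str
    cascades: dict[str, CascadeResult]
    comparisons: dict[str, ComparisonResult]
    bounds: tuple[BoundsResult, ...] = field(default_factory=tuple)


def run_model(config: ModelConfig) -> ModelReport:
    """Evaluate every scenario and compare each non-baseline to baseline."""
    specs = config.scenario_specs()
    cascades = {name: evaluate_cascade(spec) for name, spec in specs.items()}
    baseline = cascades[config.baseline_label]
    comparisons = {
        name: compare(cascade, baseline)
        for name, cascade in cascades.items()
        if name != config.baseline_label
    }
    return ModelReport(
        baseline_label=config.baseline_label,
        currency_label=config.report.currency_label,
        cascades=cascades,
        comparisons=comparisons,
    )


def run_bounds(config: ModelConfig, *, seed: int = 0) -> tuple[BoundsResult, ...]:
    """Run every interval analysis declared in the config's bounds block."""
    baseline_spec = config.scenario_spec(config.baseline_label)
    out = []
    for block in config.bounds:
        out.append(
            bounds_joint(
                config.scenario_spec(block.scenario),
                baseline_spec,
                tuple(block.intervals),
                seed=seed,
            )
        )
    return tuple(out)


def _fmt(value: float | None, kind: str, rounded: bool) -> object:
    if value is None:
        return NA
    return round_for_report(value, kind) if rounded else value


def _step_frame(report: ModelReport, rounded: bool) -> pd.DataFrame:
    rows = []
    for name, cascade in report.cascades.items():
        for res in cascade.step_results:
            rows.append(
                {
                    "scenario": name,
                    "step": res.label,
                    "proportion": res.proportion,
                    "unit_cost": res.unit_cost,
                    "persons": _fmt(res.resulting, "count", rounded),
                }
            )
    return pd.DataFrame(rows)


def _outcome_frame(report: ModelReport, rounded: bool) -> pd.DataFrame:
    rows = []
    for name, cascade in report.cascades.items():
        cmp_res = report.comparisons.get(name)
        values: dict[str, object] = {
            "cost_per_exposed": _fmt(cascade.cost_per_exposed, "currency", rounded),
            "cost_per_success": _fmt(cascade.cost_per_success, "currency", rounded),
            "incremental_cost": NA,
            "incremental_successes": NA,
            "icer": NA,
            "policy_advice": NA,
        }
        if cmp_res is not None:
            values["incremental_cost"] = _fmt(
                cmp_res.incremental_cost, "currency", rounded
            )
            values["incremental_successes"] = _fmt(
                cmp_res.incremental_successes, "count", rounded
            )
            values["icer"] = _fmt(cmp_res.icer, "currency", rounded)
            values["policy_advice"] = cmp_res.advice
        for metric in OUTCOME_METRICS:
            rows.append({"scenario": name, "metric": metric, "value": values[metric]})
    return pd.DataFrame(rows)


def _bounds_frame(bounds: tuple[BoundsResult, ...], rounded: bool) -> pd.DataFrame:
    rows = []
    for b in bounds:
        for output, env in b.outputs().items():
            kind = "count" if "successes" in output else "currency"
            rows.append(
                {
                    "scenario": b.scenario_label,
                    "output": output,
                    "lower": _fmt(env.lower, kind, rounded),
                    "upper": _fmt(env.upper, kind, rounded),
                    "method": b.method,
                    "note": env.note,
                }
            )
    return pd.DataFrame(rows)


def _render_table(report: ModelReport, rounded: bool) -> str:
    buf = io.StringIO()
    currency = report.currency_label
    buf.write(f"Filter cascade report (baseline: {report.baseline_label}, "
              f"currency: {currency})\n\n")
    buf.write("Steps\n")
    buf.write(_step_frame(report, rounded).to_string(index=False))
    buf.write("\n\nOutcomes\n")
    buf.write(_outcome_frame(report, rounded).to_string(index=False))
    if report.bounds:
        buf.write("\n\nBounds\n")
        buf.write(_bounds_frame(report.bounds, rounded).to_string(index=False))
    buf.write("\n")
    return buf.getvalue()


def _render_csv(report: ModelReport, rounded: bool) -> str:
    # object dtype keeps report-rounded integers intact through the concat
    steps = _step_frame(report, rounded).assign(section="step").astype(object)
    outcomes = _outcome_frame(report, rounded).assign(section="outcome").astype(object)
    frame = pd.concat([steps, outcomes], ignore_index=True)
    frame = frame[
        ["section", "scenario", "step", "proportion", "unit_cost",
         "persons", "metric", "value"]
    ]
    if report.bounds:
        bounds = _bounds_frame(report.bounds, rounded).assign(section="bounds")
        frame = pd.concat([frame, bounds.astype(object)], ignore_index=True)
    return frame.to_csv(index=False)


def _jsonable(value: object) -> object:
    return None if value == NA else value


def _render_jsonl(report: ModelReport, rounded: bool) -> str:
    lines = []
    for name, cascade in report.cascades.items():
        cmp_res = report.comparisons.get(name)
        record: dict[str, object] = {
            "record": "scenario",
            "scenario": name,
            "baseline": name == report.baseline_label,
            "currency": report.currency_label,
            "population": _jsonable(_fmt(cascade.population, "count", rounded)),
            "steps": [
                {
                    "step": r.label,
                    "proportion": r.proportion,
                    "unit_cost": r.unit_cost,
                    "persons": _jsonable(_fmt(r.resulting, "count", rounded)),
                    "step_cost": _jsonable(_fmt(r.step_cost, "currency", rounded)),
                }
                for r in cascade.step_results
            ],
            "successes": _jsonable(_fmt(cascade.successes, "count", rounded)),
            "total_cost": _jsonable(_fmt(cascade.total_cost, "currency", rounded)),
            "cost_per_exposed": _jsonable(
                _fmt(cascade.cost_per_exposed, "currency", rounded)
            ),
            "cost_per_success": _jsonable(
                _fmt(cascade.cost_per_success, "currency", rounded)
            ),
        }
        if cmp_res is not None:
            record["comparison"] = {
                "incremental_cost": _jsonable(
                    _fmt(cmp_res.incremental_cost, "currency", rounded)
                ),
                "incremental_successes": _jsonable(
                    _fmt(cmp_res.incremental_successes, "count", rounded)
                ),
                "icer": _jsonable(_fmt(cmp_res.icer, "currency", rounded)),
                "icer_meaningful": cmp_res.icer_meaningful,
                "quadrant": cmp_res.quadrant.value,
                "advice": cmp_res.advice,
            }
        lines.append(json.dumps(record))
    for b in report.bounds:
        lines.append(
            json.dumps(
                {
                    "record": "bounds",
                    "scenario": b.scenario_label,
                    "baseline": b.baseline_label,
                    "method": b.method,
                    "n_corners": b.n_corners,
                    "n_samples": b.n_samples,
                    "seed": b.seed,
                    "outputs": {
                        name: {"lower": env.lower, "upper": env.upper,
                               "note": env.note}
                        for name, env in b.outputs().items()
                    },
                }
            )
        )
    return "\n".join(lines) + "\n"


def render_report(
    report: ModelReport, format: str = "table", *, rounded: bool = True
) -> str:
    """Render a model report in the requested format.

    ``rounded=False`` emits full-precision values instead of whole persons
    and whole currency units.
    """
    if format == "table":
        return _render_table(report, rounded)
    if format == "csv":
        return _render_csv(report, rounded)
    if format == "jsonl":
        return _render_jsonl(report, rounded)
    raise ValueError(f"unknown report format {format!r}; expected one of {FORMATS}")
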