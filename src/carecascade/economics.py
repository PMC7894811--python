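"""Cost-effectiveness outputs: per-unit costs, incrementals, ICER, policy advice.

Scenario-versus-baseline comparison follows standard cost-effectiveness-plane
practice. Effectiveness is a dichotomous success count (e.g. remissions), so
the ICER is a cost per additional success, not a cost per QALY.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .cascade import CascadeResult

__all__ = [
    "PolicyQuadrant",
    "ComparisonResult",
    "cost_per_exposed",
    "cost_per_success",
    "compare",
    "classify_policy",
    "round_for_report",
]


class PolicyQuadrant(str, enum.Enum):
    """Position of a scenario on the cost-effectiveness plane vs baseline.

    ``dominant``: at least as effective and no more costly, with strict
    improvement on at least one axis. ``dominated``: the mirror image.
    The two ``trade_off`` quadrants require a judgement (usually via the
    ICER and a willingness-to-pay threshold, which this model does not
    impose). ``equivalent``: identical cost and effect.
    """

    dominant = "dominant"
    dominated = "dominated"
    trade_off_more_costly_more_effective = "trade_off_more_costly_more_effective"
    trade_off_less_costly_less_effective = "trade_off_less_costly_less_effective"
    equivalent = "equivalent"


#: Quadrants in which an ICER is a meaningful decision statistic.
TRADE_OFF_QUADRANTS = frozenset(
    {
        PolicyQuadrant.trade_off_more_costly_more_effective,
        PolicyQuadrant.trade_off_less_costly_less_effective,
    }
)


@dataclass(frozen=True)
class ComparisonResult:
    """Scenario-versus-baseline incrementals and classification.

    ``icer`` is ``None`` whenever incremental successes are exactly zero.
    ``icer_meaningful`` is ``True`` only in the trade-off quadrants; in
    dominance quadrants the ratio is still computed but should not drive
    a decision (the sign pattern already does).
    """

    scenario_label: str
    baseline_label: str
    incremental_cost: float
    incremental_successes: float
    icer: float | None
    icer_meaningful: bool
    quadrant: PolicyQuadrant
    advice: str


def cost_per_exposed(cascade: CascadeResult) -> float | None:
    """Cost per participant exposed to the intervention.

    Total cost divided by the cost-basis count of the costed step. With no
    costed step the scenario spends nothing and the result is 0 by
    convention. If several steps carry costs, the denominator is the
    cost-basis count of the earliest costed step (the widest exposure,
    since counts only shrink along the cascade). Returns ``None`` when a
    nonzero cost would be divided by a zero exposure.

    Under the ``post_step`` convention with a single costed step this
    equals that step's unit cost.
    """
    costed = [r for r in cascade.step_results if r.unit_cost > 0]
    if not costed:
        return 0.0
    denom = costed[0].costed_count
    if denom == 0:
        return None if cascade.total_cost > 0 else 0.0
    return cascade.total_cost / denom


def cost_per_success(cascade: CascadeResult) -> float | None:
    """Total cost divided by expected successes, at full precision.

    ``None`` when successes are zero but money was spent; 0 for any
    zero-cost scenario.
    """
    if cascade.total_cost == 0:
        return 0.0
    if cascade.successes == 0:
        return None
    return cascade.total_cost / cascade.successes


def compare(scenario: CascadeResult, baseline: CascadeResult) -> ComparisonResult:
    """Compare two evaluated cascades on the cost-effectiveness plane.

    ``baseline`` is whichever scenario the user designates as the
    comparator; comparing a cascade with itself yields the ``equivalent``
    quadrant with an undefined ICER.
    """
    d_cost = scenario.total_cost - baseline.total_cost
    d_succ = scenario.successes - baseline.successes
    quadrant, advice = classify_policy(d_cost, d_succ)
    icer = d_cost / d_succ if d_succ != 0 else None
    return ComparisonResult(
        scenario_label=scenario.scenario_label,
        baseline_label=baseline.scenario_label,
        incremental_cost=d_cost,
        incremental_successes=d_succ,
        icer=icer,
        icer_meaningful=quadrant in TRADE_OFF_QUADRANTS,
        quadrant=quadrant,
        advice=advice,
    )


def classify_policy(
    delta_cost: float, delta_successes: float
) -> tuple[PolicyQuadrant, str]:
    """Map the signs of the two incrementals to a quadrant and advice text.

    Sign patterns (Δcost, Δsuccesses):

    ==========  ==========  =============================================
    Δcost       Δsuccesses  quadrant
    ==========  ==========  =============================================
    ``+``       ``+``       trade_off_more_costly_more_effective
    ``−``       ``+``       dominant
    ``0``       ``+``       dominant (free improvement)
    ``−``       ``0``       dominant (free saving)
    ``+``       ``−``       dominated
    ``+``       ``0``       dominated (pure cost)
    ``0``       ``−``       dominated (pure loss)
    ``−``       ``−``       trade_off_less_costly_less_effective
    ``0``       ``0``       equivalent
    ==========  ==========  =============================================

    The mapping is exhaustive and mutually exclusive over all nine
    patterns. Zero means exactly zero at full precision.
    """
    if delta_cost > 0 and delta_successes > 0:
        return (
            PolicyQuadrant.trade_off_more_costly_more_effective,
            "More effective and more expensive than baseline; "
            "the ICER gives the cost of one additional success.",
        )
    if delta_cost < 0 and delta_successes < 0:
        return (
            PolicyQuadrant.trade_off_less_costly_less_effective,
            "Less effective and less expensive than baseline; "
            "the ICER gives the saving per success forgone.",
        )
    if delta_cost == 0 and delta_successes == 0:
        return (
            PolicyQuadrant.equivalent,
            "Identical cost and effectiveness to baseline.",
        )
    if delta_successes >= 0 and delta_cost <= 0:
        return (
            PolicyQuadrant.dominant,
            "Dominant: at least as effective as baseline at no extra cost.",
        )
    return (
        PolicyQuadrant.dominated,
        "Dominated: no more effective than baseline yet more costly.",
    )


def round_for_report(value: float, kind: str = "count") -> int:
    """Half-up rounding to the nearest whole person or currency unit.

    Internal arithmetic is never rounded; this is applied only when a
    report is rendered. ``kind`` is ``"count"`` or ``"currency"``; both
    round to the nearest integer (half away from zero), the distinction
    exists for call-site clarity.

    Raises
    ------
    ValueError
        For a non-finite value or an unknown ``kind``.
    """
    if kind not in ("count", "currency"):
        raise ValueError(f"unknown rounding kind {kind!r}")
    if not math.isfinite(value):
        raise ValueError(f"cannot round non-finite value {value!r}")
    # Decimal(float) is exact, so 0.5 cases resolve on the true binary value
    return int(Decimal(value).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
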