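"""Interval-bounds propagation: exactness, containment, tightening."""

import numpy as np
import pydantic
import pytest

import carecascade as cc
from carecascade import IntervalSpec, bounds_joint, bounds_one_way
from carecascade.uncertainty import ApplyTo

from test_cascade import make_scenario


@pytest.fixture(scope="module")
def depression_specs():
    cfg = cc.builtin_depression_scenarios()
    return cfg.scenario_specs()


class TestIntervalValidation:
    def test_inverted_interval_rejected(self):
        with pytest.raises(pydantic.ValidationError, match="exceeds"):
            IntervalSpec(step="s", parameter="proportion", lower=0.8, upper=0.2)

    def test_proportion_interval_must_stay_in_unit_box(self):
        with pytest.raises(pydantic.ValidationError, match=r"\[0, 1\]"):
            IntervalSpec(step="s", parameter="proportion", lower=0.5, upper=1.2)

    def test_population_interval_must_not_name_a_step(self):
        with pytest.raises(pydantic.ValidationError, match="must not name"):
            IntervalSpec(step="s", parameter="population", lower=10, upper=20)

    def test_interval_on_missing_step_rejected(self, depression_specs):
        iv = IntervalSpec(step="nonexistent", parameter="proportion", lower=0.1, upper=0.2)
        with pytest.raises(ValueError, match="does not exist"):
            bounds_one_way(
                depression_specs["filter1"], depression_specs["baseline"], iv
            )

    def test_duplicate_intervals_on_one_parameter_rejected(self, depression_specs):
        iv = IntervalSpec(step="detection", parameter="proportion", lower=0.4, upper=0.6)
        with pytest.raises(ValueError, match="more than one interval"):
            bounds_joint(
                depression_specs["filter1"], depression_specs["baseline"], [iv, iv]
            )

    def test_corner_explosion_guard(self, depression_specs):
        ivs = [
            IntervalSpec(step=s, parameter="unit_cost", lower=0, upper=1)
            for s in ("target_group", "attendance", "detection")
        ]
        with pytest.raises(ValueError, match="corner"):
            bounds_joint(
                depression_specs["filter1"],
                depression_specs["baseline"],
                ivs,
                corner_limit=2,
            )


class TestWorkedExampleEnvelopes:
    def test_detection_range_spans_baseline_and_screening_counts(self, depression_specs):
        """Varying detection over [0.47, 0.77] must recover both printed
        success counts as the envelope endpoints (costs left at zero)."""
        base = depression_specs["baseline"]
        iv = IntervalSpec(step="detection", parameter="proportion", lower=0.47, upper=0.77)
        res = bounds_one_way(base, base, iv, seed=3)
        assert cc.round_for_report(res.successes.lower) == 26_952
        assert cc.round_for_report(res.successes.upper) == 44_156

    def test_one_way_unit_cost_interval_scales_total_cost(self, depression_specs):
        scen = depression_specs["filter1"]
        detected = 15_055_403 * 0.089 * 0.81 * 0.77  # post-detection count
        iv = IntervalSpec(step="detection", parameter="unit_cost", lower=2.5, upper=10.0)
        res = bounds_one_way(scen, depression_specs["baseline"], iv, seed=3)
        assert res.total_cost.lower == pytest.approx(detected * 2.5, rel=1e-12)
        assert res.total_cost.upper == pytest.approx(detected * 10.0, rel=1e-12)

    def test_full_proportion_interval_on_final_step(self):
        scenario = make_scenario(1000.0, [0.5, 0.4])
        iv = IntervalSpec(
            step="s1", parameter="proportion", lower=0.0, upper=1.0,
            apply_to=ApplyTo.both,
        )
        res = bounds_one_way(scenario, scenario, iv)
        assert res.successes.lower == 0.0
        assert res.successes.upper == pytest.approx(500.0)  # all entrants pass

    def test_degenerate_intervals_collapse_to_point_evaluation(self, depression_specs):
        scen, base = depression_specs["filter1"], depression_specs["baseline"]
        ivs = [
            IntervalSpec(step="detection", parameter="proportion", lower=0.77, upper=0.77),
            IntervalSpec(step="detection", parameter="unit_cost", lower=5.0, upper=5.0),
        ]
        res = bounds_joint(scen, base, ivs, seed=9)
        point = cc.evaluate_cascade(scen)
        cmp = cc.compare(point, cc.evaluate_cascade(base))
        assert res.successes.lower == res.successes.upper == point.successes
        assert res.total_cost.lower == res.total_cost.upper == point.total_cost
        assert res.incremental_cost.lower == cmp.incremental_cost
        assert res.icer.lower == res.icer.upper == cmp.icer


class TestEnvelopeProperties:
    def _random_box(self, rng, scenario):
        steps = rng.choice(len(scenario.steps), size=min(3, len(scenario.steps)),
                           replace=False)
        ivs = []
        for i in steps:
            step = scenario.steps[int(i)]
            if rng.uniform() < 0.5:
                lo, hi = sorted(rng.uniform(0, 1, 2))
                ivs.append(IntervalSpec(step=step.label, parameter="proportion",
                                        lower=float(lo), upper=float(hi)))
            else:
                lo, hi = sorted(rng.uniform(0, 50, 2))
                ivs.append(IntervalSpec(step=step.label, parameter="unit_cost",
                                        lower=float(lo), upper=float(hi)))
        return ivs

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sampled_box_points_always_fall_inside_envelope(self, seed):
        """Monte-Carlo containment: random interior points never escape the
        reported envelope for any defined output."""
        rng = np.random.default_rng(seed)
        scenario = cc.random_scenario(seed + 100, n_steps_range=(3, 6))
        baseline = cc.random_scenario(seed + 200, n_steps_range=(3, 6)).model_copy(
            update={"population": scenario.population}
        )
        ivs = self._random_box(rng, scenario)
        res = bounds_joint(scenario, baseline, ivs, seed=seed)
        from carecascade.uncertainty import _evaluate_point

        for _ in range(500):
            point = np.array([rng.uniform(iv.lower, iv.upper) for iv in ivs])
            sc_res, cmp_res = _evaluate_point(scenario, baseline, tuple(ivs), point)
            checks = {
                "successes": sc_res.successes,
                "total_cost": sc_res.total_cost,
                "cost_per_success": sc_res.cost_per_success,
                "incremental_cost": cmp_res.incremental_cost,
                "incremental_successes": cmp_res.incremental_successes,
            }
            for name, value in checks.items():
                env = res.outputs()[name]
                if env.defined and value is not None:
                    assert env.lower - 1e-9 <= value <= env.upper + 1e-9, name

    def test_shrinking_an_interval_never_widens_the_envelope(self):
        scenario = cc.random_scenario(7, n_steps_range=(4, 4))
        baseline = scenario.model_copy(update={"label": "base"})
        wide = IntervalSpec(step="step1", parameter="proportion", lower=0.1, upper=0.9)
        narrow = IntervalSpec(step="step1", parameter="proportion", lower=0.3, upper=0.7)
        rw = bounds_one_way(scenario, baseline, wide, seed=5)
        rn = bounds_one_way(scenario, baseline, narrow, seed=5)
        for name in ("successes", "total_cost"):
            assert rw.outputs()[name].lower <= rn.outputs()[name].lower
            assert rn.outputs()[name].upper <= rw.outputs()[name].upper

    def test_icer_undefined_when_incremental_successes_cross_zero(self, depression_specs):
        # detection range includes the baseline value, so Δsuccesses touches 0
        iv = IntervalSpec(step="detection", parameter="proportion", lower=0.47, upper=0.77)
        res = bounds_one_way(
            depression_specs["filter1"], depression_specs["baseline"], iv, seed=2
        )
        assert not res.icer.defined
        assert "unbounded" in res.icer.note
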