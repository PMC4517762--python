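import math
import random

import pytest

from conftest import make_record
from oracles import gridsearch_oracle
from psascreen.cohort import GROUP_LABELS, assign_age_group
from psascreen.gridsearch import (
    ScenarioGrid,
    SelectionCriterion,
    evaluate_scenarios,
    select_cutoffs,
)
from psascreen.rules import new_rule
from psascreen.synthetic import default_spec, generate_cohort, separable_fixture


class TestGrid:
    def test_default_axes(self):
        grid = ScenarioGrid()
        assert grid.psa_cutoffs == (1.25, 1.75, 2.25, 2.75, 3.25, 3.75, 4.25, 4.75,
                                    5.25, 5.75, 6.0)
        assert grid.fpsa_thresholds == (15.0, 18.0, 21.0)
        assert grid.high_fpsa_cutoffs == (5.0, 6.0, math.inf)

    def test_scenario_count_by_direct_enumeration(self):
        """Independent count: 3 fPSA thresholds x sum over the 11 low
        cut-offs of the admissible high cut-offs (high >= low): the eight
        lows up to 4.75 admit all three of {5, 6, inf}, the remaining
        three admit {6, inf} only, so 3 x (8*3 + 3*2) = 90."""
        expected = 0
        grid = ScenarioGrid()
        for _ in grid.fpsa_thresholds:
            for low in grid.psa_cutoffs:
                expected += sum(1 for h in grid.high_fpsa_cutoffs if h >= low)
        assert expected == 90
        assert sum(1 for _ in grid.scenarios()) == 90

    def test_non_increasing_axis_rejected(self):
        with pytest.raises(ValueError):
            ScenarioGrid(psa_cutoffs=(2.0, 1.0))
        with pytest.raises(ValueError):
            ScenarioGrid(fpsa_thresholds=())


class TestEvaluate:
    def test_one_result_per_group_scenario(self, synthetic_cohort):
        results = evaluate_scenarios(synthetic_cohort)
        assert len(results) == 4 * 90

    def test_minimal_cutoff_has_full_sensitivity(self, synthetic_cohort):
        grid = ScenarioGrid(psa_cutoffs=(1e-9,), fpsa_thresholds=(18.0,),
                            high_fpsa_cutoffs=(1e-9,))
        for res in evaluate_scenarios(synthetic_cohort, grid):
            assert res.summary.sensitivity.point == 1.0

    def test_sensitivity_monotone_in_low_cutoff(self, synthetic_cohort):
        """Within fixed fPSA threshold and high cut-off, sensitivity is
        non-increasing in the low cut-off."""
        results = evaluate_scenarios(synthetic_cohort)
        by_slice = {}
        for r in results:
            by_slice.setdefault(
                (r.group_label, r.fpsa_threshold, r.psa_high), []
            ).append(r)
        for slice_results in by_slice.values():
            ordered = sorted(slice_results, key=lambda r: r.psa_low)
            sens = [r.summary.sensitivity.point for r in ordered]
            assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))

    def test_single_class_group_propagates_undefined(self):
        recs = [make_record(age=45, psa=3.0, fpsa=10.0, pid=str(i)) for i in range(5)]
        results = evaluate_scenarios(recs)
        assert results and all(r.summary.sensitivity is None for r in results)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            evaluate_scenarios([])


class TestSelect:
    def test_planted_rule_recovered(self):
        cohort = separable_fixture(new_rule(), 30, seed=3)
        outcome = select_cutoffs(evaluate_scenarios(cohort))
        rule = outcome.rule
        assert rule is not None
        for g in GROUP_LABELS:
            assert rule.groups[g] == new_rule().groups[g]

    def test_edge_of_grid_rule_recovered(self):
        """A rule planted at the 1.25 ng/mL grid edge is recovered."""
        edge = new_rule()
        edge = type(edge)(
            name="edge",
            groups={**dict(edge.groups),
                    "<=49": type(edge.groups["<=49"])(21.0, 1.25, 5.0)},
        )
        cohort = separable_fixture(edge, 30, seed=4)
        outcome = select_cutoffs(evaluate_scenarios(cohort))
        assert outcome.rule.groups["<=49"].psa_cutoff_low_fpsa == 1.25

    def test_impossible_floor_reports_infeasible(self, synthetic_cohort):
        outcome = select_cutoffs(
            evaluate_scenarios(synthetic_cohort),
            SelectionCriterion(sensitivity_floor=1.0),
        )
        # some group misses at least one cancer at every scenario
        assert any(sel.infeasible for sel in outcome.per_group.values())
        assert outcome.rule is None

    def test_selection_permutation_invariant(self):
        cohort = separable_fixture(new_rule(), 30, seed=5)
        results = evaluate_scenarios(cohort)
        shuffled = results[:]
        random.Random(0).shuffle(shuffled)
        a = select_cutoffs(results)
        b = select_cutoffs(shuffled)
        for g in GROUP_LABELS:
            assert a.per_group[g].chosen == b.per_group[g].chosen

    def test_raising_floor_never_raises_selected_specificity(self, synthetic_cohort):
        """A stricter feasibility floor shrinks the feasible set, so the
        attainable specificity can only drop (or the group go infeasible)."""
        results = evaluate_scenarios(synthetic_cohort)
        best_spec = {}
        for floor in (0.80, 0.88, 0.95):
            outcome = select_cutoffs(results, SelectionCriterion(sensitivity_floor=floor))
            for g, sel in outcome.per_group.items():
                spec = None if sel.infeasible else sel.chosen.summary.specificity.point
                if g in best_spec and spec is not None:
                    assert best_spec[g] is not None and spec <= best_spec[g] + 1e-12
                best_spec[g] = spec

    def test_agrees_with_brute_force_oracle(self):
        """On a small cohort, selection matches an independent loop-based
        re-implementation of the whole scenario sweep."""
        spec = default_spec(seed=6)
        from dataclasses import replace

        small = {g: replace(gp, n=50) for g, gp in spec.groups.items()}
        cohort = generate_cohort(
            type(spec)(groups=small, seed=6, rp_fraction=0.0, rp_params=None)
        )
        assert len(cohort) == 200
        grid = ScenarioGrid()
        outcome = select_cutoffs(evaluate_scenarios(cohort, grid),
                                 SelectionCriterion(sensitivity_floor=0.88))
        want = gridsearch_oracle(cohort, list(grid.scenarios()), floor=0.88)
        for g in GROUP_LABELS:
            sel = outcome.per_group[g]
            got = None if sel.infeasible else (
                sel.chosen.fpsa_threshold, sel.chosen.psa_low, sel.chosen.psa_high
            )
            assert got == want[g]

    def test_tie_break_prefers_higher_npv_then_lower_cutoff(self):
        """Construct two scenarios tied on specificity and PPV but not NPV:
        the higher NPV wins regardless of input order."""
        from psascreen.diagnostics import ConfusionMatrix, metrics
        from psascreen.gridsearch import ScenarioResult

        def scen(low, cm):
            return ScenarioResult("<=49", 18.0, low, 6.0, cm, metrics(cm), cm.tp + cm.fp)

        # a and d tie on specificity (0.5) and PPV (0.5); d has NPV 20/21 > 10/12
        a = scen(2.25, ConfusionMatrix(tp=10, fp=10, tn=10, fn=2))
        d = scen(2.75, ConfusionMatrix(tp=20, fp=20, tn=20, fn=1))
        # b and c tie with a on every metric; only the low cut-off differs
        b = scen(1.75, ConfusionMatrix(tp=5, fp=5, tn=5, fn=1))
        c = scen(3.25, ConfusionMatrix(tp=20, fp=20, tn=20, fn=4))
        for ordering in ([a, d], [d, a]):
            out = select_cutoffs(ordering, SelectionCriterion(sensitivity_floor=0.5))
            assert out.per_group["<=49"].chosen is d
        # with npv also tied, the lower low cut-off wins
        for ordering in ([a, b, c], [c, b, a], [b, a, c]):
            out = select_cutoffs(ordering, SelectionCriterion(sensitivity_floor=0.5))
            assert out.per_group["<=49"].chosen is b
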