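import math
from fractions import Fraction

import numpy as np
import pytest

from conftest import make_record
from oracles import clopper_pearson_oracle
from psascreen import reference as ref
from psascreen.cohort import GROUP_LABELS, BiopsyGS, PathStage, RPPathology
from psascreen.diagnostics import (
    ConfusionMatrix,
    clopper_pearson,
    confusion,
    metrics,
    predictive_values_from_rates,
    recognition_table,
)
from psascreen.rules import BiopsyRule, GroupRule, new_rule
from psascreen.synthetic import separable_fixture
from psascreen._util import pct


def flag_everyone():
    return BiopsyRule(
        "all", {g: GroupRule(50.0, 1e-9, 1e-9) for g in GROUP_LABELS}
    )


class TestConfusion:
    def test_four_way_cross_tab(self, four_record_cohort):
        cm = confusion(four_record_cohort, new_rule())
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 1, 1)
        assert cm.n == 4

    def test_all_benign_none_flagged(self):
        recs = [make_record(age=60, psa=0.5, fpsa=10.0, pid=str(i)) for i in range(7)]
        cm = confusion(recs, new_rule())
        assert (cm.tp, cm.fp, cm.fn) == (0, 0, 0) and cm.tn == 7

    def test_planted_fixture_has_no_false_negatives(self):
        cm = confusion(separable_fixture(new_rule(), 30, seed=1), new_rule())
        assert cm.fn == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion([], new_rule())


class TestMetrics:
    def test_published_youngest_group_historical_row(self):
        """Counts reconstructed for the youngest stratum (61 cancers, 117
        benign) under the historical rule reproduce the published
        93.4/7.7/34.5/69.2 percent row."""
        summ = metrics(ConfusionMatrix(tp=57, fn=4, tn=9, fp=108))
        assert pct(summ.sensitivity.point) == 93.4
        assert pct(summ.specificity.point) == 7.7
        assert pct(summ.ppv.point) == 34.5
        assert pct(summ.npv.point) == 69.2

    def test_undefined_metrics_are_none_not_zero(self):
        summ = metrics(ConfusionMatrix(tp=0, fn=0, tn=5, fp=5))
        assert summ.sensitivity is None
        assert summ.specificity is not None

    def test_degenerate_all_flagged(self):
        summ = metrics(ConfusionMatrix(tp=10, fn=0, tn=0, fp=10))
        assert summ.sensitivity.point == 1.0
        assert summ.specificity.point == 0.0
        assert summ.ppv.point == 0.5
        assert summ.npv is None

    @pytest.mark.parametrize("seed", range(5))
    def test_bayes_identity_rational(self, seed):
        """PPV from counts equals sens*pi / (sens*pi + (1-spec)(1-pi))
        exactly in rational arithmetic."""
        rng = np.random.default_rng(seed)
        for _ in range(50):
            tp, fp, tn, fn = (int(x) for x in rng.integers(1, 200, size=4))
            cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
            sens = Fraction(tp, tp + fn)
            spec = Fraction(tn, tn + fp)
            pi = Fraction(tp + fn, cm.n)
            bayes = sens * pi / (sens * pi + (1 - spec) * (1 - pi))
            assert Fraction(tp, tp + fp) == bayes


class TestClopperPearson:
    def test_boundaries(self):
        assert clopper_pearson(0, 20)[0] == 0.0
        assert clopper_pearson(20, 20)[1] == 1.0

    def test_interval_contains_point(self):
        lo, hi = clopper_pearson(57, 61)
        assert lo <= 57 / 61 <= hi

    @pytest.mark.parametrize("k,n", [(57, 61), (0, 20), (20, 20), (1, 2), (5, 100)])
    def test_matches_tail_sum_oracle(self, k, n):
        """Beta-quantile interval agrees with brute-force bisection on the
        two one-sided exact binomial tail conditions."""
        got = clopper_pearson(k, n)
        want = clopper_pearson_oracle(k, n)
        assert got == pytest.approx(want, abs=1e-4)

    @pytest.mark.parametrize("k,n", [(-1, 10), (11, 10), (0, 0)])
    def test_invalid_counts_rejected(self, k, n):
        with pytest.raises(ValueError):
            clopper_pearson(k, n)


class TestPredictiveValueBridge:
    @pytest.mark.parametrize(
        "sens,spec,n_mal,n_ben,ppv,npv",
        [
            (88.5, 32.7, 338, 150, 74.8, 55.7),  # oldest group, revised rule
            (90.8, 17.8, 524, 438, 56.9, 61.9),  # 60-69, revised rule
            (100.0, 100.0, 10, 10, 100.0, 100.0),
        ],
    )
    def test_bridge_examples(self, sens, spec, n_mal, n_ben, ppv, npv):
        assert predictive_values_from_rates(sens, spec, n_mal, n_ben) == (ppv, npv)

    @pytest.mark.parametrize("label", ["<=49", "60-69", ">=70"])
    def test_historical_rows_reproducible(self, label):
        """The historical-rule PPV/NPV cells of three of the four groups
        follow from their rounded rates (the 50-59 row does not; its
        printed predictive values are inconsistent with its rates)."""
        sens, spec, ppv, npv = ref.OLD_RULE_RATES[label]
        got = predictive_values_from_rates(
            sens, spec, ref.MALIGNANT_COUNTS[label], ref.BENIGN_COUNTS[label]
        )
        assert got == (ppv, npv)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            predictive_values_from_rates(105.0, 50.0, 10, 10)


class TestRecognitionTable:
    def _cohort(self):
        recs = []
        for i, gs in enumerate([BiopsyGS.GS8, BiopsyGS.GS8, BiopsyGS.GS6]):
            recs.append(make_record(age=65, psa=9.0, fpsa=10.0, malignant=True,
                                    gs=gs, pid=f"m{i}"))
        recs.append(make_record(age=65, psa=1.0, fpsa=10.0, malignant=True,
                                gs=BiopsyGS.GS6, pid="m-low",
                                rp=RPPathology(stage=PathStage.ORGAN_CONFINED)))
        recs.append(make_record(age=65, psa=3.0, fpsa=10.0, pid="b0"))
        return recs

    def test_high_grade_above_cutoffs_fully_recognized(self):
        table = recognition_table(self._cohort(), new_rule())
        assert table.loc["GS8", "60-69"] == 1.0
        assert table.loc["GS8", "total"] == 1.0

    def test_empty_category_is_no_data(self):
        table = recognition_table(self._cohort(), new_rule())
        assert math.isnan(table.loc["GS10", "60-69"])
        assert math.isnan(table.loc["GS10", "total"])

    def test_missed_low_psa_tumor_lowers_fraction(self):
        table = recognition_table(self._cohort(), new_rule())
        assert table.loc["GS<=6", "60-69"] == 0.5
        assert table.loc["<=pT2c", "60-69"] == 0.0  # the RP record has PSA 1.0

    def test_flag_everyone_rule_recognizes_all_nonempty_categories(self):
        table = recognition_table(self._cohort(), flag_everyone())
        filled = table.stack()
        assert (filled == 1.0).all()

    def test_planted_fixture_fully_recognized(self):
        table = recognition_table(separable_fixture(new_rule(), 30, seed=2), new_rule())
        assert (table.stack() == 1.0).all()


class TestCutoffMonotonicity:
    def test_raising_low_cutoff_never_increases_tp_or_fp(self, synthetic_cohort):
        """With the fPSA threshold fixed, stricter PSA cut-offs can only
        shrink the flagged set: specificity rises, sensitivity falls."""
        base = new_rule()
        prev_tp = prev_fp = None
        for delta in (0.0, 0.5, 1.0, 2.0):
            rule = BiopsyRule(
                f"shift{delta}",
                {
                    g: GroupRule(gr.fpsa_threshold, gr.psa_cutoff_low_fpsa + delta,
                                 gr.psa_cutoff_high_fpsa + delta)
                    for g, gr in base.groups.items()
                },
            )
            cm = confusion(synthetic_cohort, rule)
            if prev_tp is not None:
                assert cm.tp <= prev_tp and cm.fp <= prev_fp
            prev_tp, prev_fp = cm.tp, cm.fp
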