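"""Accuracy and agreement statistics against independent oracles.

Sensitivity/specificity/kappa are invariant to permuting patients, so the
exhaustive small-n oracle checks iterate over every 2x2 confusion
configuration rather than every labeled vector; Mann-Whitney is checked
against a brute-force pairwise-comparison count.
"""

import itertools
import math

import numpy as np
import pytest

from ocutriage import (
    EvaluationError,
    UndefinedMetricError,
    adjudicate,
    cohens_kappa,
    confusion,
    evaluate_records,
    is_urgent_24h,
    kappa_band,
    mann_whitney_u,
    mcnemar_cc,
    odds_ratio,
    sensitivity,
    specificity,
    summarize_cohort,
)
from ocutriage.acuity import AcuityLevel
from ocutriage.stats import ConfusionCounts


def vectors_from_counts(tp, fp, fn, tn):
    pred = [True] * tp + [True] * fp + [False] * fn + [False] * tn
    gold = [True] * tp + [False] * fp + [True] * fn + [False] * tn
    return pred, gold


class TestDichotomization:
    def test_urgent_iff_top_two_bands(self):
        urgent = {level for level in AcuityLevel if is_urgent_24h(level)}
        assert urgent == {AcuityLevel.EMERGENCY_SAME_DAY,
                          AcuityLevel.URGENT_24H}

    def test_sub_48h_changes_never_flip_a_non_urgent_label(self):
        for level in (AcuityLevel.SOON_48H, AcuityLevel.ROUTINE_WEEK,
                      AcuityLevel.SELF_CARE):
            assert not is_urgent_24h(level)


class TestAdjudication:
    def test_agreement_stands_without_tiebreak(self):
        rec = adjudicate(True, True)
        assert rec.adjudicated is True and rec.tiebreak is None

    def test_disagreement_settled_by_casting_vote(self):
        rec = adjudicate(True, False, tiebreak=False)
        assert rec.adjudicated is False

    def test_missing_tiebreak_on_disagreement_rejected(self):
        with pytest.raises(EvaluationError, match="no tiebreak"):
            adjudicate(True, False)

    def test_spurious_tiebreak_on_agreement_rejected(self):
        with pytest.raises(EvaluationError, match="spurious"):
            adjudicate(False, False, tiebreak=True)


class TestConfusion:
    def test_perfect_prediction_on_study_margins(self):
        pred, gold = vectors_from_counts(53, 0, 0, 156)
        counts = confusion(pred, gold)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (53, 0, 0, 156)

    def test_tool_arm_reconstruction_from_printed_counts(self):
        # 53 gold-urgent of 209; 40 predicted urgent among them; 67 urgent overall
        pred, gold = vectors_from_counts(40, 27, 13, 129)
        counts = confusion(pred, gold)
        assert counts == ConfusionCounts(tp=40, fp=27, fn=13, tn=129)
        assert counts.n == 209

    def test_empty_inputs_give_zero_counts(self):
        assert confusion([], []).n == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(EvaluationError):
            confusion([True], [True, False])


class TestSensitivitySpecificity:
    @pytest.mark.parametrize("tp,fn,expected", [
        (40, 13, 75.5),      # tool arm
        (41, 12, 77.4),      # optometry arm: 41/53 = 77.36
    ])
    def test_sensitivity_matches_printed_values(self, tp, fn, expected):
        counts = ConfusionCounts(tp=tp, fp=0, fn=fn, tn=0)
        assert round(sensitivity(counts), 1) == expected

    def test_tool_specificity_matches_printed_value(self):
        counts = ConfusionCounts(tp=0, fp=27, fn=0, tn=129)
        assert round(specificity(counts), 1) == 82.7

    def test_empty_class_is_an_error_not_zero(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(ConfusionCounts(0, 5, 0, 5))
        with pytest.raises(UndefinedMetricError):
            specificity(ConfusionCounts(5, 0, 5, 0))


def chi2_sf_oracle(x):
    """Independent chi-square(1) upper tail: P(X > x) = erfc(sqrt(x/2))."""
    return math.erfc(math.sqrt(x / 2.0))


class TestMcNemar:
    def test_balanced_discordance(self):
        res = mcnemar_cc(5, 5)
        assert res.statistic == pytest.approx(0.1)
        assert res.p_value == pytest.approx(0.752, abs=5e-4)

    def test_no_discordant_pairs_convention(self):
        res = mcnemar_cc(0, 0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_one_sided_discordance(self):
        res = mcnemar_cc(20, 0)
        assert res.statistic == pytest.approx(18.05)
        assert res.p_value < 0.001

    @pytest.mark.parametrize("b,c", [(1, 0), (3, 7), (12, 12), (40, 9),
                                     (0, 2), (100, 60)])
    def test_statistic_and_tail_match_closed_forms(self, b, c):
        res = mcnemar_cc(b, c)
        assert res.statistic == (abs(b - c) - 1) ** 2 / (b + c)
        assert res.p_value == pytest.approx(chi2_sf_oracle(res.statistic),
                                            abs=1e-10)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(5, 5), (20, 0), (7, 13), (1, 4)]:
            sm = sm_mcnemar([[0, b], [c, 0]], exact=False, correction=True)
            ours = mcnemar_cc(b, c)
            assert ours.statistic == pytest.approx(float(sm.statistic))
            assert ours.p_value == pytest.approx(float(sm.pvalue))

    def test_negative_counts_rejected(self):
        with pytest.raises(EvaluationError):
            mcnemar_cc(-1, 2)


class TestKappa:
    def test_identical_non_constant_vectors_give_kappa_one(self):
        labels = [True, False, True, True, False]
        res = cohens_kappa(labels, labels)
        assert res.kappa == pytest.approx(1.0)
        assert res.band == "almost perfect"

    def test_study_agreement_table_hand_oracle(self):
        # 2x2 agreement table [[40,13],[27,129]], n=209:
        # p_o = 169/209, p_e = (67*53 + 142*156)/209^2
        a, b = vectors_from_counts(40, 27, 13, 129)
        res = cohens_kappa(a, b)
        p_o = 169 / 209
        p_e = (67 * 53 + 142 * 156) / 209 ** 2
        assert res.kappa == pytest.approx((p_o - p_e) / (1 - p_e))
        assert res.kappa == pytest.approx(0.535, abs=5e-4)
        assert res.band == "moderate"

    def test_both_raters_constant_identical_is_undefined(self):
        with pytest.raises(EvaluationError, match="undefined"):
            cohens_kappa([True, True, True], [True, True, True])

    def test_agrees_with_sklearn_exhaustively(self):
        """Point estimate matches sklearn on every 2x2 configuration, n <= 12."""
        from sklearn.metrics import cohen_kappa_score

        for n in range(2, 13):
            for tp, fp, fn in itertools.product(range(n + 1), repeat=3):
                tn = n - tp - fp - fn
                if tn < 0:
                    continue
                a, b = vectors_from_counts(tp, fp, fn, tn)
                pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n ** 2
                if pe >= 1 - 1e-15:
                    continue
                ours = cohens_kappa(a, b).kappa
                ref = cohen_kappa_score(np.array(a), np.array(b))
                assert ours == pytest.approx(ref, abs=1e-12)

    def test_random_labelers_center_on_zero(self):
        """Mean kappa of independent uniform raters is ~0 (10,000 pairs, n=200)."""
        rng = np.random.default_rng(11)
        n, reps = 200, 10_000
        a = rng.random((reps, n)) < 0.5
        b = rng.random((reps, n)) < 0.5
        tp = (a & b).sum(axis=1)
        tn = (~a & ~b).sum(axis=1)
        po = (tp + tn) / n
        pa = a.mean(axis=1)
        pb = b.mean(axis=1)
        pe = pa * pb + (1 - pa) * (1 - pb)
        kappas = (po - pe) / (1 - pe)
        assert abs(kappas.mean()) < 0.02
        # spot-check the vectorized recomputation against the implementation
        res = cohens_kappa(a[0], b[0])
        assert res.kappa == pytest.approx(kappas[0])


class TestKappaBands:
    @pytest.mark.parametrize("value,expected", [
        (-0.3, "no agreement"), (0.0, "no agreement"),
        (0.01, "none to slight"), (0.20, "none to slight"),
        (0.21, "fair"), (0.26, "fair"), (0.40, "fair"),
        (0.41, "moderate"), (0.60, "moderate"),
        (0.61, "substantial"), (0.75, "substantial"), (0.80, "substantial"),
        (0.81, "almost perfect"), (1.0, "almost perfect"),
    ])
    def test_a_priori_cut_points(self, value, expected):
        assert kappa_band(value) == expected


def mwu_brute_force(a, b):
    """Pairwise wins for group a, ties counted one half."""
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u


class TestMannWhitney:
    def test_identical_multisets_are_indistinguishable(self):
        stat, p = mann_whitney_u([3, 3, 4, 5, 5], [3, 3, 4, 5, 5])
        assert stat == mwu_brute_force([3, 3, 4, 5, 5], [3, 3, 4, 5, 5])
        assert p > 0.95

    def test_complete_separation_gives_zero_u_for_low_group(self):
        stat, _ = mann_whitney_u([1, 1, 1], [5, 5, 5])
        assert stat == 0.0

    def test_fully_tied_groups_give_u_eight(self):
        stat, _ = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert stat == 8.0  # brute force: 6 wins + 4 ties * 0.5

    def test_u_statistic_matches_brute_force_on_binary_configs(self):
        """Exhaustive over binary-score group compositions up to n = 12."""
        for n_a in range(1, 7):
            for n_b in range(1, 7):
                for ones_a in range(n_a + 1):
                    for ones_b in range(n_b + 1):
                        a = [1] * ones_a + [0] * (n_a - ones_a)
                        b = [1] * ones_b + [0] * (n_b - ones_b)
                        stat, _ = mann_whitney_u(a, b)
                        assert stat == pytest.approx(mwu_brute_force(a, b))

    def test_empty_group_rejected(self):
        with pytest.raises(EvaluationError):
            mann_whitney_u([], [1, 2])


class TestOddsRatio:
    def test_symmetric_table_gives_unity(self):
        est, _ = odds_ratio(10, 10, 10, 10)
        assert est == pytest.approx(1.0)

    def test_closed_form(self):
        est, _ = odds_ratio(20, 10, 10, 20)
        assert est == pytest.approx(4.0)

    def test_woolf_interval_hand_oracle(self):
        est, (lo, hi) = odds_ratio(13, 39, 40, 117)
        assert est == pytest.approx((13 * 117) / (39 * 40))
        se = math.sqrt(1 / 13 + 1 / 39 + 1 / 40 + 1 / 117)
        assert lo == pytest.approx(est * math.exp(-1.959963984540054 * se))
        assert hi == pytest.approx(est * math.exp(1.959963984540054 * se))

    def test_zero_cell_uses_haldane_anscombe(self):
        est, (lo, hi) = odds_ratio(5, 0, 3, 7)
        expected = (5.5 * 7.5) / (0.5 * 3.5)
        assert est == pytest.approx(expected)
        assert 0 < lo < est < hi

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.contingency_tables import Table2x2

        t = Table2x2([[13, 39], [40, 117]])
        est, (lo, hi) = odds_ratio(13, 39, 40, 117)
        assert est == pytest.approx(t.oddsratio)
        ref_lo, ref_hi = t.oddsratio_confint()
        assert lo == pytest.approx(ref_lo)
        assert hi == pytest.approx(ref_hi)


class TestSummaries:
    def test_single_patient_degenerate_summary(self):
        import pandas as pd

        out = summarize_cohort(pd.DataFrame({"age": [40]}))
        assert out["age"] == {"mean": 40.0, "sd": 0.0, "min": 40.0, "max": 40.0}

    def test_feedback_top2_proportion(self):
        import pandas as pd

        likert = [5] * 70 + [4] * 51 + [3] * 20 + [2] * 4 + [1] * 2
        likert += [np.nan] * (209 - len(likert))
        out = summarize_cohort(pd.DataFrame({"likert": likert}))
        fb = out["feedback"]
        assert fb["respondents"] == 147
        assert fb["top2"] == 121
        assert round(100 * fb["top2_proportion"]) == 82


class TestExhaustiveOracleEquivalence:
    def test_sens_spec_kappa_match_brute_force_on_all_small_instances(self):
        """Every 2x2 confusion configuration with n <= 12, recomputed naively."""
        for n in range(1, 13):
            for tp, fp, fn in itertools.product(range(n + 1), repeat=3):
                tn = n - tp - fp - fn
                if tn < 0:
                    continue
                pred, gold = vectors_from_counts(tp, fp, fn, tn)
                counts = confusion(pred, gold)
                assert (counts.tp, counts.fp, counts.fn, counts.tn) == \
                    (tp, fp, fn, tn)
                if tp + fn > 0:
                    naive = 100 * sum(p and g for p, g in zip(pred, gold)) / \
                        sum(gold)
                    assert sensitivity(counts) == pytest.approx(naive)
                if tn + fp > 0:
                    naive = 100 * sum((not p) and (not g)
                                      for p, g in zip(pred, gold)) / \
                        (len(gold) - sum(gold))
                    assert specificity(counts) == pytest.approx(naive)


class TestEvaluateRecords:
    def test_paired_bookkeeping_reuses_one_adjudicated_vector(self):
        import pandas as pd

        frame = pd.DataFrame({
            "tool_urgent": [True, False, True, False],
            "opt_urgent": [True, True, False, False],
            "reviewer1_urgent": [True, False, True, False],
            "reviewer2_urgent": [True, True, True, False],
            "tiebreak_urgent": [np.nan, True, np.nan, np.nan],
        })
        result = evaluate_records(frame)
        assert result["gold_urgent"] == 3
        tool = result["arms"]["tool"]
        assert (tool["tp"], tool["fn"]) == (2, 1)
        mc = result["mcnemar"]["sensitivity"]
        assert mc.b + mc.c <= 3  # discordance restricted to gold-positives
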