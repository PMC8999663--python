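"""Statistical kernels against brute-force oracles and reference libraries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score, roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from ctperf import (
    ConfusionMatrix,
    DegenerateStatisticError,
    InputError,
    cohen_kappa,
    confusion_metrics,
    delong_paired_test,
    effective_dose,
    empirical_auc,
    icc_absolute_agreement,
    mann_whitney_u,
    paired_t_test,
    reconstruct_confusion,
    wilson_ci,
    youden_cutoff,
)
from ctperf.diagnostics import round_half_up


def pairwise_auc_oracle(scores, labels, lower_is_abnormal=True):
    """AUC by exhaustive pos x neg pair counting (wins + half ties)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos, neg = s[y], s[~y]
    wins = 0.0
    for a in pos:
        for b in neg:
            if (a < b) if lower_is_abnormal else (a > b):
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (pos.size * neg.size)


# ---------------------------------------------------------------------------
# Wilson intervals and confusion metrics
# ---------------------------------------------------------------------------

class TestWilson:
    @pytest.mark.parametrize("k, n", [(49, 63), (283, 337), (40, 63), (1, 10),
                                      (0, 10), (63, 63), (32, 63), (290, 337)])
    def test_matches_statsmodels(self, k, n):
        ci = wilson_ci(k, n)
        lo, hi = proportion_confint(k, n, method="wilson")
        assert ci.lower == pytest.approx(lo, abs=1e-12)
        assert ci.upper == pytest.approx(hi, abs=1e-12)
        assert ci.lower <= ci.estimate <= ci.upper

    def test_printed_interval_49_of_63(self):
        ci = wilson_ci(49, 63)
        assert round_half_up(100 * ci.lower) == 66
        assert round_half_up(100 * ci.upper) == 86

    def test_printed_lower_bound_283_of_337(self):
        assert round_half_up(100 * wilson_ci(283, 337).lower) == 80

    def test_all_successes_boundary(self):
        ci = wilson_ci(63, 63)
        assert round_half_up(100 * ci.upper) == 100
        assert ci.lower < 1.0

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            wilson_ci(1, 0)
        with pytest.raises(InputError):
            wilson_ci(5, 3)


class TestConfusionMetrics:
    def test_mpr_row_counts(self):
        m = confusion_metrics(ConfusionMatrix(tp=49, fp=54, fn=14, tn=283))
        assert round_half_up(100 * m["ppv"].estimate) == 48
        assert round_half_up(100 * m["npv"].estimate) == 95

    def test_visual_row_counts(self):
        m = confusion_metrics(ConfusionMatrix(tp=42, fp=34, fn=21, tn=303))
        assert round_half_up(100 * m["ppv"].estimate) == 55

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionMatrix(tp=10, fp=0, fn=0, tn=10))
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            assert m[name].estimate == 1.0

    def test_zero_denominator_flags_only_that_metric(self):
        m = confusion_metrics(ConfusionMatrix(tp=0, fp=0, fn=5, tn=10))
        assert m["ppv"] is None
        assert m["sensitivity"] is not None

    def test_reconstruction_round_half_up(self):
        cm = reconstruct_confusion(78, 84, 63, 337)
        assert (cm.tp, cm.tn) == (49, 283)
        cm = reconstruct_confusion(51, 86, 63, 337)
        assert (cm.tp, cm.tn) == (32, 290)
        cm = reconstruct_confusion(100, 100, 10, 10)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (10, 10, 0, 0)


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong / Youden
# ---------------------------------------------------------------------------

class TestAUC:
    def test_perfect_separation(self):
        scores = [0.5, 0.6, 0.7, 1.0, 1.1, 1.2]
        labels = [1, 1, 1, 0, 0, 0]
        assert empirical_auc(scores, labels).auc == 1.0

    def test_ties_against_pair_oracle(self):
        scores = [1, 1, 2, 3, 3, 4, 5, 5]
        labels = [1, 0, 1, 1, 0, 0, 1, 0]
        res = empirical_auc(scores, labels)
        assert res.auc == pytest.approx(pairwise_auc_oracle(scores, labels),
                                        abs=1e-12)

    @given(st.data())
    def test_pair_oracle_property(self, data):
        n = data.draw(st.integers(4, 50))
        scores = data.draw(st.lists(st.integers(0, 12), min_size=n, max_size=n))
        n_pos = data.draw(st.integers(1, n - 1))
        labels = [1] * n_pos + [0] * (n - n_pos)
        res = empirical_auc(scores, labels)
        assert res.auc == pytest.approx(pairwise_auc_oracle(scores, labels),
                                        abs=1e-12)
        assert res.auc_ci[0] <= res.auc <= res.auc_ci[1]

    def test_matches_sklearn(self, rng):
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        res = empirical_auc(scores, labels, direction="lower_is_abnormal")
        assert res.auc == pytest.approx(roc_auc_score(labels, -scores), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=40)
        labels = np.r_[np.ones(15, bool), np.zeros(25, bool)]
        a = empirical_auc(scores, labels).auc
        b = empirical_auc(np.exp(scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            empirical_auc([1, 2, 3], [1, 1, 1])


class TestDeLong:
    def test_identical_scores_give_p_one(self, rng):
        scores = rng.normal(size=30)
        labels = np.r_[np.ones(12, bool), np.zeros(18, bool)]
        res = delong_paired_test(scores, scores, labels)
        assert res.difference == 0.0
        assert res.p_value == 1.0

    def test_rank_invariance_of_difference(self, rng):
        scores = rng.normal(size=30)
        labels = np.r_[np.ones(12, bool), np.zeros(18, bool)]
        res = delong_paired_test(scores, np.tanh(scores), labels)
        assert res.difference == pytest.approx(0.0, abs=1e-12)

    def test_single_auc_variance_nonnegative_and_cov_psd(self, rng):
        a = rng.normal(size=40)
        b = a + rng.normal(0, 0.5, size=40)
        labels = rng.random(40) < 0.4
        labels[:2] = [True, False]
        res = delong_paired_test(a, b, labels)
        assert res.variance >= 0.0
        ra = empirical_auc(a, labels)
        assert ra.auc_ci[1] >= ra.auc_ci[0]

    def test_detects_a_clearly_better_parameter(self, rng):
        labels = np.r_[np.ones(60, bool), np.zeros(140, bool)]
        good = np.r_[rng.normal(0.6, 0.15, 60), rng.normal(1.0, 0.15, 140)]
        bad = rng.normal(1.0, 0.3, 200)
        res = delong_paired_test(good, bad, labels)
        assert res.auc_a > res.auc_b
        assert res.p_value < 0.01


class TestYouden:
    def test_complete_separation_midpoint(self):
        scores = [0.5, 0.6, 0.7, 0.9, 1.0, 1.1]
        labels = [1, 1, 1, 0, 0, 0]
        cutoff, j, sens, spec = youden_cutoff(scores, labels)
        assert cutoff == pytest.approx(0.8)
        assert j == pytest.approx(1.0)
        assert (sens, spec) == (1.0, 1.0)

    def test_all_equal_scores(self):
        cutoff, j, sens, spec = youden_cutoff([5, 5, 5, 5], [1, 0, 1, 0])
        assert j == 0.0

    def test_exhaustive_scan_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 50))
            scores = rng.integers(0, 10, n).astype(float)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                labels[0] = ~labels[0]
            _, j, _, _ = youden_cutoff(scores, labels)
            # brute force over a dense threshold grid
            grid = np.linspace(scores.min() - 1, scores.max() + 1, 2000)
            best = -np.inf
            y = labels
            for c in grid:
                call = scores < c
                sens = (call & y).sum() / y.sum()
                spec = (~call & ~y).sum() / (~y).sum()
                best = max(best, sens + spec - 1)
            assert j == pytest.approx(best, abs=1e-12)


# ---------------------------------------------------------------------------
# Rank/agreement statistics
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = mann_whitney_u([10, 11, 12], [1, 2, 3, 4])
        assert u == 12.0  # n_a * n_b

    def test_identical_multisets(self):
        a = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney_u(a, a)
        assert u == pytest.approx(len(a) ** 2 / 2)

    def test_all_pairs_enumeration_oracle(self, rng):
        for _ in range(20):
            a = rng.integers(0, 8, int(rng.integers(3, 12))).astype(float)
            b = rng.integers(0, 8, int(rng.integers(3, 12))).astype(float)
            u, _ = mann_whitney_u(a, b)
            brute = sum(1.0 if x > y else 0.5 if x == y else 0.0
                        for x in a for y in b)
            assert u == pytest.approx(brute, abs=1e-9)

    def test_p_matches_scipy_asymptotic(self, rng):
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.7, 1, 30)
        _, p = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True).pvalue
        assert p == pytest.approx(ref, rel=1e-9)


class TestKappa:
    def test_identical_raters(self):
        calls = [0, 1, 0, 1, 1, 0]
        assert cohen_kappa(calls, calls).value == pytest.approx(1.0)

    def test_hand_built_table(self):
        # agreement table a=30 (both+), b=10 (A+ B-), c=5 (A- B+), d=55
        a = [1] * 30 + [1] * 10 + [0] * 5 + [0] * 55
        b = [1] * 30 + [0] * 10 + [1] * 5 + [0] * 55
        # p_o = 0.85; p_e = 0.40*0.35 + 0.60*0.65 = 0.53
        expected = (0.85 - 0.53) / (1 - 0.53)
        res = cohen_kappa(a, b)
        assert res.value == pytest.approx(expected, abs=1e-12)
        assert res.value == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_independent_random_calls_near_zero(self, rng):
        a = rng.random(5000) < 0.5
        b = rng.random(5000) < 0.5
        assert abs(cohen_kappa(a, b).value) < 0.05

    def test_constant_identical_raters_undefined(self):
        res = cohen_kappa([1, 1, 1], [1, 1, 1])
        assert res.undefined


class TestICC:
    def test_perfect_agreement(self):
        x = np.arange(10.0)
        res = icc_absolute_agreement(np.column_stack([x, x]))
        assert res.value == pytest.approx(1.0)

    def test_pure_noise_near_zero(self, rng):
        x = rng.normal(0, 1, 500)
        y = rng.normal(0, 1, 500)
        assert abs(icc_absolute_agreement(np.column_stack([x, y])).value) < 0.15

    def test_manual_anova_oracle_ten_targets(self):
        rng = np.random.default_rng(3)
        a = rng.normal(100, 15, 10)
        ratings = np.column_stack([a, a + rng.normal(1.0, 4.0, 10)])
        n, k = ratings.shape
        grand = ratings.mean()
        msr = k * ((ratings.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((ratings.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = ((ratings - ratings.mean(axis=1, keepdims=True)
                - ratings.mean(axis=0, keepdims=True) + grand) ** 2).sum() \
            / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        res = icc_absolute_agreement(ratings)
        assert res.value == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin_icc2(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(9)
        a = rng.normal(1.0, 0.2, 24)
        ratings = np.column_stack([a, a + rng.normal(0, 0.08, 24)])
        res = icc_absolute_agreement(ratings)
        long = pd.DataFrame({
            "target": np.repeat(np.arange(24), 2),
            "rater": np.tile(["r1", "r2"], 24),
            "score": ratings.ravel(),
        })
        ref = pg.intraclass_corr(long, targets="target", raters="rater",
                                 ratings="score")
        # pingouin's ICC(A,1) is the two-way absolute-agreement single-measure
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert res.value == pytest.approx(row["ICC"], abs=1e-9)
        assert res.ci[0] == pytest.approx(row[ci_col][0], abs=5.1e-3)
        assert res.ci[1] == pytest.approx(row[ci_col][1], abs=5.1e-3)

    def test_too_few_targets_rejected(self):
        with pytest.raises(InputError):
            icc_absolute_agreement(np.ones((3, 2)))


class TestPairedT:
    def test_identical_samples(self):
        assert paired_t_test([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_constant_shift_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            paired_t_test([6, 7, 8], [1, 2, 3])

    def test_matches_scipy(self, rng):
        a = rng.normal(80, 8, 10)
        b = rng.normal(65, 10, 10)
        t, p = paired_t_test(a, b)
        ref = sps.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)


class TestEffectiveDose:
    def test_dlp_conversion(self):
        assert effective_dose(754.4) == pytest.approx(10.5616)
        assert effective_dose(0.0) == 0.0
        assert effective_dose(100.0) == pytest.approx(1.4)

    def test_negative_dlp_rejected(self):
        with pytest.raises(InputError):
            effective_dose(-1.0)
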