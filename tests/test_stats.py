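"""Statistics layer: agreement, exact intervals, ROC/DeLong, comparisons."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score, roc_auc_score

import memclinic as mc
from memclinic.stats import round_percent


class TestCohensKappa:
    def test_identical_raters_give_one(self):
        labels = ["a", "b", "c", "a", "b"] * 10
        assert mc.cohens_kappa(labels, labels).estimate == pytest.approx(1.0)

    def test_hand_computed_2x2_table(self):
        # {a=45, b=5, c=5, d=45}: p_o = 0.9, p_e = 0.5 -> kappa = 0.8
        a = ["pos"] * 50 + ["neg"] * 50
        b = ["pos"] * 45 + ["neg"] * 5 + ["pos"] * 5 + ["neg"] * 45
        assert mc.cohens_kappa(a, b).estimate == pytest.approx(0.8)

    def test_matches_sklearn_on_random_multiclass(self):
        rng = np.random.default_rng(0)
        a = rng.choice(list("xyz"), 300)
        b = rng.choice(list("xyz"), 300)
        ours = mc.cohens_kappa(a, b).estimate
        assert ours == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_null_kappa_near_zero_for_independent_raters(self):
        rng = np.random.default_rng(1)
        n = 10_000
        a = rng.choice(["p", "q"], n)
        b = rng.choice(["p", "q"], n)
        se = 1 / math.sqrt(n)  # asymptotic null SE is ~1/sqrt(n) for 2 classes
        assert abs(mc.cohens_kappa(a, b).estimate) < 3 * se

    def test_symmetric_and_relabel_invariant(self):
        rng = np.random.default_rng(2)
        a = rng.choice(list("uvw"), 200)
        b = rng.choice(list("uvw"), 200)
        k1 = mc.cohens_kappa(a, b).estimate
        assert k1 == pytest.approx(mc.cohens_kappa(b, a).estimate)
        relabel = {"u": "1", "v": "2", "w": "3"}
        k2 = mc.cohens_kappa([relabel[x] for x in a], [relabel[x] for x in b])
        assert k1 == pytest.approx(k2.estimate)

    def test_constant_equal_raters_defined_as_one(self):
        with pytest.warns(UserWarning):
            res = mc.cohens_kappa(["a"] * 5, ["a"] * 5)
        assert res.estimate == 1.0

    def test_one_vs_rest_collapse(self):
        a = ["MSD", "MCI_MD", "HS_SCI_WW", "MSD"]
        collapsed = mc.collapse_one_vs_rest(a, "MSD")
        assert list(collapsed) == ["MSD", "rest", "rest", "MSD"]


class TestExactBinomialCI:
    @pytest.mark.parametrize("k,n,low,high", [
        (102, 112, 84, 96),   # published causal-hypothesis accuracy CI
        (132, 149, 82, 93),   # published progression sensitivity CI
    ])
    def test_published_interval_rounding(self, k, n, low, high):
        lo, hi = mc.exact_binomial_ci(k, n, 0.95)
        assert (round_percent(lo), round_percent(hi)) == (low, high)

    def test_boundary_cases_exact(self):
        assert mc.exact_binomial_ci(0, 10)[0] == 0.0
        assert mc.exact_binomial_ci(10, 10)[1] == 1.0

    def test_interval_nesting_90_in_95(self):
        for n in range(1, 51, 7):
            for k in range(0, n + 1, max(1, n // 4)):
                l90, h90 = mc.exact_binomial_ci(k, n, 0.90)
                l95, h95 = mc.exact_binomial_ci(k, n, 0.95)
                assert l95 <= l90 and h90 <= h95

    def test_zero_n_rejected(self):
        with pytest.raises(mc.ValidationError):
            mc.exact_binomial_ci(0, 0)


class TestDiagnosticMetrics:
    def test_published_progression_counts(self):
        # MRI+cognitive progression table: 132/149, 157/192, 289/341
        counts = mc.ConfusionCounts(tp=132, fn=17, tn=157, fp=35)
        m = mc.diagnostic_metrics(counts)
        assert (m["sensitivity"].numerator, m["sensitivity"].denominator) == (132, 149)
        assert m["sensitivity"].percent == 89
        assert m["specificity"].percent == 82
        assert m["accuracy"].percent == 85
        assert m["accuracy"].numerator == 289 and m["accuracy"].denominator == 341

    def test_perfect_classifier(self):
        m = mc.diagnostic_metrics(mc.ConfusionCounts(tp=20, fp=0, tn=30, fn=0))
        assert all(r.percent == 100 and r.ci_high == 1.0 for r in m.values())

    def test_zero_denominator_omitted(self):
        with pytest.warns(UserWarning):
            m = mc.diagnostic_metrics(mc.ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert "sensitivity" not in m and "specificity" in m

    def test_percent_rounding_half_away_from_zero(self):
        assert round_percent(0.845) == 85 and round_percent(0.8449) == 84
        assert round_percent(-0.005) == -1
        assert round_percent(100 / 112 / 100 * 100, 1) == 89.3


class TestRocAucDelong:
    def test_perfectly_ordered_scores(self):
        res = mc.roc_auc_delong([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.estimate == 1.0 and res.ci_high == 1.0

    @given(st.lists(st.tuples(st.integers(0, 4), st.booleans()),
                    min_size=4, max_size=12).filter(
        lambda v: 0 < sum(lab for _, lab in v) < len(v)))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_auc_equals_brute_force_pairwise(self, pairs):
        scores = np.array([s for s, _ in pairs], dtype=float)
        labels = np.array([l for _, l in pairs])
        pos, neg = scores[labels], scores[~labels]
        brute = np.mean([(p > q) + 0.5 * (p == q)
                         for p, q in itertools.product(pos, neg)])
        ours = mc.roc_auc_delong(scores, labels).estimate
        assert ours == pytest.approx(brute, abs=1e-12)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 200)
        s = rng.normal(size=200) + y
        assert mc.roc_auc_delong(s, y).estimate == pytest.approx(
            roc_auc_score(y, s), abs=1e-12)

    def test_identical_paired_scores_give_p_one(self):
        rng = np.random.default_rng(4)
        y = np.array([0, 1] * 20)
        s = rng.normal(size=40)
        diff, p = mc.delong_paired_test(s, s, y)
        assert diff == 0.0 and p == 1.0

    def test_paired_test_detects_dominant_classifier(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 400)
        good = y + rng.normal(0, 0.3, 400)
        bad = rng.normal(size=400)
        diff, p = mc.delong_paired_test(good, bad, y)
        assert diff > 0.2 and p < 1e-6

    def test_single_class_rejected(self):
        with pytest.raises(mc.ValidationError):
            mc.roc_auc_delong([0.2, 0.5], [1, 1])


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([3.0, 1.0, 5.0, 9.0, 2.0])
        assert mc.spearman_rho(x, np.exp(x)).estimate == pytest.approx(1.0)

    def test_hand_rank_computation(self):
        # rank differences d = (-1, 1, -1, 1, 0), sum d^2 = 4:
        # rho = 1 - 6*4/(5*(25-1)) = 0.8
        res = mc.spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.estimate == pytest.approx(0.8)

    def test_null_distribution(self):
        rng = np.random.default_rng(6)
        n = 10_000
        res = mc.spearman_rho(rng.normal(size=n), rng.normal(size=n))
        assert abs(res.estimate) < 3 / math.sqrt(n)

    def test_constant_vector_signalled(self):
        with pytest.raises(mc.ValidationError):
            mc.spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])


class TestGroupCompare:
    def test_identical_groups_nonsignificant(self):
        v = list(range(10)) * 2
        g = ["a"] * 10 + ["b"] * 10
        test, p, pb = mc.group_compare(v, g)
        assert p > 0.99 and pb == 1.0

    def test_bonferroni_multiplication(self):
        rng = np.random.default_rng(7)
        v = np.concatenate([rng.normal(0, 1, 30), rng.normal(3, 1, 30)])
        g = ["a"] * 30 + ["b"] * 30
        _, p, pb = mc.group_compare(v, g, m_tests=60)
        assert pb == pytest.approx(min(1.0, 60 * p))

    def test_gaussian_data_uses_t_test_skewed_uses_mwu(self):
        rng = np.random.default_rng(8)
        gauss = np.concatenate([rng.normal(0, 1, 50), rng.normal(1, 1, 50)])
        skew = np.concatenate([rng.exponential(1, 50) ** 3,
                               rng.exponential(2, 50) ** 3])
        g = ["a"] * 50 + ["b"] * 50
        assert mc.group_compare(gauss, g)[0] == "t-test"
        assert mc.group_compare(skew, g)[0] == "mann-whitney"

    def test_type_one_error_at_nominal_level(self):
        """Null rejections near 5% over repeated Gaussian draws."""
        rng = np.random.default_rng(9)
        reps = 2000
        rejections = 0
        g = ["a"] * 12 + ["b"] * 12
        for _ in range(reps):
            v = rng.normal(size=24)
            _, p, _ = mc.group_compare(v, g)
            rejections += p < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 0.02

    def test_degenerate_group_signalled(self):
        with pytest.raises(mc.ValidationError):
            mc.group_compare([1, 1, 1, 2, 2, 2], ["a"] * 3 + ["b"] * 3)


class TestPercentDifference:
    @pytest.mark.parametrize("ref,other,expect", [
        (27.48, 24.14, 12.15),     # global-screen row
        (0.90, 3.00, -233.33),     # FAQ finances row
        (8.13, 7.36, 9.47),        # hippocampal volume row
        (5.0, 5.0, 0.0),
    ])
    def test_published_rows(self, ref, other, expect):
        assert mc.percent_difference(ref, other) == expect

    def test_zero_reference_signalled(self):
        with pytest.raises(mc.ValidationError):
            mc.percent_difference(0.0, 1.0)
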