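"""ROC inference against independent oracles: brute-force pair counting,
exact permutation enumeration, sklearn's AUC, and a paired permutation test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from conftest import brute_force_auc
from mscsf import roc


class TestAuroc:
    def test_hand_counted_example(self):
        # 9 pairs, one inversion (0.4 < 0.7): 8/9
        scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
        labels = [1, 1, 1, 0, 0, 0]
        assert roc.auroc(scores, labels).auc == pytest.approx(8 / 9)
        assert brute_force_auc(scores, labels) == pytest.approx(8 / 9)

    def test_all_tied_scores_give_half(self):
        assert roc.auroc([1.0] * 6, [1, 1, 1, 0, 0, 0]).auc == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            roc.auroc([0.1, 0.2], [1, 1])

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_and_sklearn(self, data):
        n = data.draw(st.integers(4, 50))
        n_pos = data.draw(st.integers(1, n - 1))
        # coarse grid to force ties
        scores = data.draw(
            st.lists(st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.5, 0.9, 1.0]),
                     min_size=n, max_size=n)
        )
        labels = np.zeros(n, bool)
        labels[:n_pos] = True
        got = roc.auroc(scores, labels).auc
        assert got == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_antisymmetry_without_ties(self, rng):
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        labels[0], labels[1] = True, False
        a = roc.auroc(scores, labels).auc
        b = roc.auroc(-scores, labels).auc
        assert a + b == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        labels = np.r_[np.ones(15, bool), np.zeros(25, bool)]
        a = roc.auroc(scores, labels).auc
        b = roc.auroc(np.exp(3 * scores) + 7, labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_equals_trapezoid_under_curve(self, rng):
        scores = np.round(rng.random(60), 1)  # ties included
        labels = rng.random(60) < 0.4
        labels[:2] = [True, False]
        fpr, tpr = roc.roc_curve_points(scores, labels)
        assert fpr[0] == 0 and tpr[-1] == 1
        area = np.trapezoid(tpr, fpr)
        assert area == pytest.approx(roc.auroc(scores, labels).auc, abs=1e-12)


class TestMasonGraham:
    def test_perfect_separation_n4_exact(self):
        # all C(4,2)=6 assignments; only one puts both positives on top
        p = roc.mason_graham_p([3, 4, 1, 2], [1, 1, 0, 0])
        assert p == pytest.approx(1 / 6)

    def test_auc_half_not_significant(self):
        # pos {1, 4} vs neg {2, 3}: AUC exactly 0.5
        scores = [1, 2, 3, 4]
        labels = [1, 0, 0, 1]
        assert roc.auroc(scores, labels).auc == 0.5
        assert roc.mason_graham_p(scores, labels) >= 0.5

    def test_normal_approx_close_to_exact_all_splits_of_10(self, rng):
        """Tie-corrected normal approximation vs full enumeration across every
        two-class split of 10 distinct scores."""
        scores = rng.normal(size=10)
        worst = 0.0
        for n_pos in range(2, 9):
            for combo in itertools.combinations(range(10), n_pos):
                labels = np.zeros(10, bool)
                labels[list(combo)] = True
                exact = roc.mason_graham_p(scores, labels, exact_max_n=12)
                approx = roc.mason_graham_p(scores, labels, exact_max_n=0)
                worst = max(worst, abs(exact - approx))
        assert worst < 0.02

    def test_large_auc_gives_tiny_p(self, rng):
        pos = rng.normal(2.2, 1, 96)
        neg = rng.normal(0, 1, 64)
        scores = np.r_[pos, neg]
        labels = np.r_[np.ones(96, bool), np.zeros(64, bool)]
        p = roc.mason_graham_p(scores, labels)
        assert p < 1e-10

    def test_two_sided_doubles_smaller_tail(self):
        scores = list(range(20))
        labels = [0] * 10 + [1] * 10  # positives hold the top ranks: AUC = 1
        one = roc.mason_graham_p(scores, labels)
        two = roc.mason_graham_p(scores, labels, alternative="two-sided")
        assert two == pytest.approx(min(1.0, 2 * one))


class TestDeLong:
    def test_identical_scores_p_one(self, rng):
        s = rng.normal(size=40)
        y = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        a, b, z, p = roc.delong_paired_test(s, s, y)
        assert a == b and z == 0.0 and p == 1.0

    def test_monotone_transform_equal_aucs(self, rng):
        s = rng.normal(size=40)
        y = np.r_[np.ones(15, bool), np.zeros(25, bool)]
        a, b, z, p = roc.delong_paired_test(s, np.tanh(s) * 5 + 2, y)
        assert a == pytest.approx(b)
        assert p == pytest.approx(1.0)

    def test_symmetry_in_arguments(self, rng):
        sa, sb = rng.normal(size=30), rng.normal(size=30)
        y = np.r_[np.ones(12, bool), np.zeros(18, bool)]
        a1, b1, z1, p1 = roc.delong_paired_test(sa, sb, y)
        a2, b2, z2, p2 = roc.delong_paired_test(sb, sa, y)
        assert (a1, b1) == (b2, a2)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_agrees_with_permutation_oracle_small_n(self, rng):
        """On 8 paired cases, the DeLong p should be close to a
        swap-the-pair permutation p."""
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
        sa = rng.normal(size=8) + y * 1.5
        sb = rng.normal(size=8) + y * 0.3
        _, _, _, p_delong = roc.delong_paired_test(sa, sb, y)
        observed = abs(roc.auroc(sa, y).auc - roc.auroc(sb, y).auc)
        gt = eq = 0
        n_perm = 5000
        for _ in range(n_perm):
            swap = rng.random(8) < 0.5
            pa = np.where(swap, sb, sa)
            pb = np.where(swap, sa, sb)
            diff = abs(roc.auroc(pa, y).auc - roc.auroc(pb, y).auc)
            if diff > observed + 1e-12:
                gt += 1
            elif abs(diff - observed) <= 1e-12:
                eq += 1
        # mid-p: half-credit permutations tied at the observed statistic, the
        # discrete analogue of a continuous two-sided p
        p_perm = (gt + 0.5 * eq) / n_perm
        assert abs(p_delong - p_perm) < 0.05


class TestBootstrap:
    def test_perfect_separation_upper_is_one(self):
        scores = [0.9, 0.8, 0.7, 0.2, 0.1, 0.05]
        labels = [1, 1, 1, 0, 0, 0]
        res = roc.bootstrap_auc_ci(scores, labels, n_boot=200, seed=3)
        assert res.ci_upper == 1.0

    def test_seed_reproducibility(self, rng):
        scores = rng.normal(size=40)
        labels = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        r1 = roc.bootstrap_auc_ci(scores, labels, n_boot=300, seed=11)
        r2 = roc.bootstrap_auc_ci(scores, labels, n_boot=300, seed=11)
        assert (r1.ci_lower, r1.ci_upper) == (r2.ci_lower, r2.ci_upper)

    def test_small_n_boot_warns(self, rng):
        scores = rng.normal(size=20)
        labels = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        with pytest.warns(UserWarning, match="n_boot"):
            roc.bootstrap_auc_ci(scores, labels, n_boot=50, seed=0)

    def test_bca_brackets_point_estimate(self, rng):
        scores = rng.normal(size=50) + np.r_[np.ones(20), np.zeros(30)]
        labels = np.r_[np.ones(20, bool), np.zeros(30, bool)]
        res = roc.bootstrap_auc_ci(scores, labels, n_boot=400, seed=5, method="bca")
        assert res.ci_lower <= res.auc <= res.ci_upper


class TestConfusion:
    def test_perfect_classifier(self):
        m = roc.confusion_at_cutoff([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert m.sensitivity == 1.0 and m.specificity == 1.0 and m.accuracy == 1.0

    def test_cutoff_zero_calls_everything_positive(self):
        m = roc.confusion_at_cutoff([0.9, 0.6, 0.3, 0.1], [1, 1, 0, 0], cutoff=0.0)
        assert m.sensitivity == 1.0 and m.specificity == 0.0

    def test_tie_at_cutoff_goes_negative(self):
        m = roc.confusion_at_cutoff([0.5, 0.6], [1, 0], cutoff=0.5)
        assert m.fn == 1  # the positive at exactly 0.5 is called negative

    def test_rates_satisfy_their_definitions(self, rng):
        scores = rng.random(100)
        labels = rng.random(100) < 0.6
        labels[:2] = [True, False]
        m = roc.confusion_at_cutoff(scores, labels, cutoff=0.4)
        assert m.sensitivity == m.tp / (m.tp + m.fn)
        assert m.specificity == m.tn / (m.tn + m.fp)
        assert m.ppv == m.tp / (m.tp + m.fp)
        assert m.npv == m.tn / (m.tn + m.fn)
        assert m.accuracy == (m.tp + m.tn) / 100


class TestGroupedAuroc:
    def test_single_group_equals_pooled(self, rng):
        scores = rng.normal(size=30)
        labels = np.r_[np.ones(10, bool), np.zeros(20, bool)]
        out = roc.auroc_by_group(scores, labels, np.ones(30, int))
        assert out[1].auc == out["pooled"].auc

    def test_identical_groups_identical_aucs(self, rng):
        scores = rng.normal(size=20)
        labels = np.r_[np.ones(8, bool), np.zeros(12, bool)]
        s2 = np.r_[scores, scores]
        y2 = np.r_[labels, labels]
        g = np.r_[np.ones(20, int), np.full(20, 2)]
        out = roc.auroc_by_group(s2, y2, g)
        assert out[1].auc == pytest.approx(out[2].auc)

    def test_one_class_group_skipped_with_warning(self, rng):
        scores = rng.normal(size=12)
        labels = np.r_[np.ones(4, bool), np.zeros(4, bool), np.zeros(4, bool)]
        groups = np.r_[np.ones(8, int), np.full(4, 2)]
        with pytest.warns(UserWarning, match="lacks one class"):
            out = roc.auroc_by_group(scores, labels, groups)
        assert 2 not in out and 1 in out
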