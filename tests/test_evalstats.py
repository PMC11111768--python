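"""Metric oracles: set-counting Dice, brute-force HD95, enumeration Wilcoxon,
Mann-Whitney AUC, exhaustive Youden scan, DeLong basics."""

import itertools

import numpy as np
import pytest
from scipy import stats

from neuroquant.evalstats import (
    delong_compare,
    dice_coefficient,
    hd95,
    retest_relative_difference,
    roc_auc,
    wilcoxon_paired,
    youden_operating_point,
)


def _random_mask(rng, shape=(12, 12, 12), p=0.1):
    m = rng.random(shape) < p
    if not m.any():
        m[tuple(rng.integers(0, s) for s in shape)] = True
    return m


def _hd95_bruteforce(a, b, spacing):
    """O(n^2) all-pairs boundary-distance oracle."""
    from neuroquant.evalstats import boundary_voxels

    pa = boundary_voxels(a) * np.asarray(spacing)
    pb = boundary_voxels(b) * np.asarray(spacing)
    d_ab = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1)).min(axis=1)
    d_ba = np.sqrt(((pb[:, None, :] - pa[None, :, :]) ** 2).sum(-1)).min(axis=1)
    return max(np.percentile(d_ab, 95), np.percentile(d_ba, 95))


class TestDice:
    def test_identical_and_disjoint(self):
        a = np.zeros((5, 5, 5), bool)
        a[1:3] = True
        assert dice_coefficient(a, a) == 100.0
        assert dice_coefficient(a, ~a) == 0.0

    def test_both_empty_scores_100_one_empty_0(self):
        e = np.zeros((4, 4, 4), bool)
        f = e.copy()
        f[0, 0, 0] = True
        assert dice_coefficient(e, e) == 100.0
        assert dice_coefficient(e, f) == 0.0

    def test_half_overlap_counting(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, :4] = True
        b[0, 0, 2:], b[0, 1, :2] = True, True
        assert dice_coefficient(a, b) == pytest.approx(50.0)

    def test_symmetry_and_permutation_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b = _random_mask(rng), _random_mask(rng)
            assert dice_coefficient(a, b) == dice_coefficient(b, a)
            perm = (2, 0, 1)
            assert dice_coefficient(a.transpose(perm), b.transpose(perm)) == \
                dice_coefficient(a, b)


class TestHD95:
    def test_identical_masks_zero(self):
        m = np.zeros((6, 6, 6), bool)
        m[2:4, 2:4, 2:4] = True
        assert hd95(m, m) == 0.0

    def test_single_voxel_pair_distance(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[1, 1, 1], b[1, 1, 4] = True, True
        assert hd95(a, b) == pytest.approx(3.0)
        # anisotropy-aware: 2 mm slices double the z gap
        assert hd95(a, b, spacing=(1, 1, 2)) == pytest.approx(6.0)

    def test_empty_mask_rejected(self):
        m = np.zeros((4, 4, 4), bool)
        f = m.copy()
        f[1, 1, 1] = True
        with pytest.raises(ValueError, match="empty"):
            hd95(m, f)

    def test_matches_bruteforce_oracle_on_random_pairs(self):
        rng = np.random.default_rng(1)
        spacing = (1.0, 1.5, 2.0)
        for _ in range(50):
            a, b = _random_mask(rng, p=0.15), _random_mask(rng, p=0.15)
            assert hd95(a, b, spacing) == pytest.approx(
                _hd95_bruteforce(a, b, spacing), abs=1e-9)


class TestRetest:
    def test_equal_volumes_zero(self):
        assert retest_relative_difference(5.0, 5.0) == 0.0

    def test_explicit_denominator(self):
        assert retest_relative_difference(110.0, 90.0, 100.0) == pytest.approx(20.0)

    def test_default_denominator_is_pair_mean(self):
        assert retest_relative_difference(110.0, 90.0) == pytest.approx(20.0)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            retest_relative_difference(1.0, 2.0, 0.0)


class TestWilcoxon:
    def test_exact_enumeration_oracle_n12(self):
        # all differences positive, no ties: two-sided p = 2/2^12
        rng = np.random.default_rng(2)
        x = rng.standard_normal(12)
        y = x + rng.uniform(0.5, 1.5, 12)
        p, flags = wilcoxon_paired(y, x)
        # independent enumeration over all 2^12 sign assignments
        d = np.sort(np.abs(y - x))
        ranks = np.arange(1, 13)
        w_obs = ranks.sum()  # all positive
        stats_all = [sum(r for r, s in zip(ranks, signs) if s)
                     for signs in itertools.product([0, 1], repeat=12)]
        stats_all = np.array(stats_all)
        p_enum = min(1.0, 2 * min((stats_all >= w_obs).mean(),
                                  (stats_all <= w_obs).mean()))
        assert p == pytest.approx(p_enum, abs=1e-12)
        assert flags["significant_0.001"]

    def test_all_zero_differences_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="nonzero"):
            wilcoxon_paired(x, x)

    def test_large_sample_matches_scipy_normal_approx(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(60)
        y = x + rng.standard_normal(60) * 0.3 + 0.1
        p, _ = wilcoxon_paired(x, y)
        ref = stats.wilcoxon(x - y, method="approx", correction=True).pvalue
        assert p == pytest.approx(float(ref))


class TestROC:
    def test_perfect_and_tied(self):
        assert roc_auc([1, 2, 10, 11], [0, 0, 1, 1]) == 1.0
        assert roc_auc([5, 5, 5, 5], [0, 0, 1, 1]) == 0.5

    def test_one_swap_counting(self):
        assert roc_auc([1, 3, 2, 4], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_mann_whitney_identity_on_random_sets(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(8, 40))
            scores = np.round(rng.standard_normal(n), 1)  # induce ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            u = stats.mannwhitneyu(scores[labels], scores[~labels],
                                   alternative="two-sided").statistic
            expected = u / (labels.sum() * (~labels).sum())
            assert roc_auc(scores, labels) == pytest.approx(float(expected), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestYouden:
    def test_perfect_separation(self):
        res = youden_operating_point([0.1, 0.2, 0.9, 1.0], [0, 0, 1, 1])
        assert res.sensitivity == res.specificity == res.accuracy == 1.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            scores = rng.standard_normal(10)
            labels = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], bool)
            res = youden_operating_point(scores, labels)
            best_j = max(
                ((scores >= t) & labels).sum() / 5 + ((scores < t) & ~labels).sum() / 5 - 1
                for t in scores
            )
            j = res.sensitivity + res.specificity - 1
            assert j == pytest.approx(best_j, abs=1e-12)

    def test_sign_reversal_symmetry(self):
        rng = np.random.default_rng(6)
        scores = rng.standard_normal(20)
        labels = rng.random(20) < 0.5
        labels[0], labels[1] = True, False
        a = youden_operating_point(scores, labels)
        b = youden_operating_point(-scores, ~labels)
        ja = a.sensitivity + a.specificity - 1
        jb = b.sensitivity + b.specificity - 1
        assert ja == pytest.approx(jb, abs=1e-12)


class TestDeLong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(7)
        s = rng.standard_normal(40)
        labels = np.r_[np.zeros(20), np.ones(20)].astype(bool)
        res = delong_compare(s, s, labels)
        assert res["delta"] == 0.0
        assert res["p"] == 1.0
        assert res["degenerate"]

    def test_auc_matches_roc_auc(self):
        rng = np.random.default_rng(8)
        labels = rng.random(50) < 0.4
        labels[:2] = [True, False]
        s1, s2 = rng.standard_normal(50), rng.standard_normal(50)
        res = delong_compare(s1, s2, labels)
        assert res["auc1"] == pytest.approx(roc_auc(s1, labels))
        assert res["auc2"] == pytest.approx(roc_auc(s2, labels))

    def test_detects_genuinely_better_score(self):
        rng = np.random.default_rng(9)
        labels = np.r_[np.zeros(60), np.ones(60)].astype(bool)
        signal = labels.astype(float) * 2.0
        good = signal + rng.standard_normal(120) * 0.5
        bad = rng.standard_normal(120)
        res = delong_compare(good, bad, labels)
        assert res["p"] < 0.001
        assert res["delta"] > 0
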