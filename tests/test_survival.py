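import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from iciscore.survival import (bh_adjust, chi_square_table, km_estimate, kruskal_wallis,
                               logrank_test, logrank_z, optimal_cutpoint, spearman,
                               wilcoxon_rank_sum)


class TestKaplanMeier:
    def test_all_events_empirical_survival(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        np.testing.assert_allclose(km.survival, [0.75, 0.5, 0.25, 0.0])
        assert km.median == 2

    def test_all_censored_median_not_reached(self):
        km = km_estimate([5, 6, 7], [0, 0, 0])
        assert km.survival.size == 0
        assert km.median is None
        assert km.survival_at(100) == 1.0

    def test_mixed_six_record_product_limit(self):
        # hand-computed: events at 1,3,4,6 with risk sets 6,4,3,1
        times = [1, 2, 3, 4, 5, 6]
        events = [1, 0, 1, 1, 0, 1]
        km = km_estimate(times, events)
        np.testing.assert_allclose(km.survival, [5 / 6, 5 / 8, 5 / 12, 0.0])
        assert km.median == 4

    def test_nonincreasing_and_starts_at_one(self, rng):
        t = rng.exponential(50, 40)
        e = rng.integers(0, 2, 40)
        km = km_estimate(t, e)
        assert km.survival_at(0) == 1.0 or km.times.min() == 0
        assert (np.diff(km.survival) <= 1e-12).all()

    def test_matches_lifelines(self, rng):
        t = rng.exponential(100, 60)
        e = rng.integers(0, 2, 60)
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for et, s in zip(km.times, km.survival):
            assert kmf.predict(et) == pytest.approx(s, abs=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 0, 1, 1, 1, 0, 1, 1]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_four_subjects(self):
        # group A: event@1, censor@4; group B: event@2, censor@5
        # O_A - E_A = 1/6, Var = 1/4 + 2/9 = 17/36 -> chi2 = 1/17
        t = [1, 4, 2, 5]
        e = [1, 0, 1, 0]
        g = [0, 0, 1, 1]
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(1 / 17, rel=1e-12)

    def test_matches_lifelines_three_groups(self, rng):
        t = rng.exponential(80, 90)
        g = rng.integers(0, 3, 90)
        t[g == 2] *= 0.4
        e = rng.integers(0, 2, 90)
        mine = logrank_test(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-8)
        assert mine.p_value == pytest.approx(ref.p_value, rel=1e-6)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestOptimalCutpoint:
    def test_single_admissible_candidate_returned(self):
        score = np.array([1.0, 1.0, 1.0, 1.0, 2.0, 2.0, 2.0, 2.0])
        t = [3, 5, 7, 9, 11, 13, 15, 17]
        e = [1, 1, 0, 1, 0, 1, 1, 0]
        cut = optimal_cutpoint(score, t, e, minprop=0.4)
        assert cut.threshold == 1.0
        assert cut.n_high == 4 and cut.n_low == 4

    def test_perfect_separation_threshold_between_blocs(self, rng):
        n = 30
        score = np.concatenate([rng.uniform(0, 1, 15), rng.uniform(3, 4, 15)])
        t = np.concatenate([rng.uniform(5, 20, 15), rng.uniform(200, 400, 15)])
        e = np.ones(n, dtype=int)
        cut = optimal_cutpoint(score, t, e)
        assert 0 < cut.threshold < 3
        assert score[score <= cut.threshold].max() < 1.5

    def test_equals_bruteforce_over_admissible_candidates(self, rng):
        for rep in range(8):
            n = int(rng.integers(15, 61))
            score = rng.normal(size=n)
            t = rng.exponential(100 * np.exp(-0.5 * score))
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                e[0] = 1
            cut = optimal_cutpoint(score, t, e, minprop=0.1)
            best = None
            for thr in np.unique(score)[:-1]:
                high = score > thr
                if min(high.sum(), n - high.sum()) < 0.1 * n:
                    continue
                z = logrank_z(t, e, high.astype(int))
                if best is None or abs(z) > abs(best[1]):
                    best = (float(thr), z)
            assert cut.threshold == pytest.approx(best[0])
            assert abs(cut.standardized_statistic) == pytest.approx(abs(best[1]))

    def test_minprop_unsatisfiable_rejected(self):
        with pytest.raises(ValueError):
            optimal_cutpoint([1.0, 1.0, 1.0, 2.0], [1, 2, 3, 4], [1, 1, 1, 1], minprop=0.4)

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError):
            optimal_cutpoint([1.0, 1.0], [1, 2], [1, 1])


class TestRankTests:
    def test_wilcoxon_exact_one_sided(self):
        _, p = wilcoxon_rank_sum([1, 2], [3, 4], alternative="less")
        assert p == pytest.approx(1 / 6)

    def test_spearman_perfectly_monotone(self):
        rho, _ = spearman([1, 2, 3, 4], [10, 20, 25, 90])
        assert rho == pytest.approx(1.0)

    def test_bh_step_up_oracle(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_kruskal_detects_shift(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0, 1, 40)
        c = rng.normal(2, 1, 40)
        _, p = kruskal_wallis(a, b, c)
        assert p < 1e-4

    def test_chi_square_independent_table(self):
        stat, p = chi_square_table([[25, 25], [25, 25]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1, 2])
        with pytest.raises(ValueError):
            kruskal_wallis([1.0], [])
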