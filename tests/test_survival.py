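"""Kaplan-Meier, log-rank, univariate Cox, and the min-p cutpoint search."""

import numpy as np
import pytest
from scipy import stats

from ihcmark.survival import (
    km_estimate,
    logrank_test,
    cox_univariate,
    cox_score_statistic,
    optimal_survival_cutpoint,
    minp_permutation_adjust,
)
from conftest import random_survival_fixture


def naive_logrank(times_a, events_a, times_b, events_b):
    """Independent oracle: direct observed/expected tabulation over pooled
    event times with the hypergeometric variance."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, bool)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, bool)
    o_minus_e = v = 0.0
    for u in sorted(set(np.concatenate([ta[ea], tb[eb]]))):
        n1 = (ta >= u).sum()
        n2 = (tb >= u).sum()
        d1 = ((ta == u) & ea).sum()
        d2 = ((tb == u) & eb).sum()
        n, d = n1 + n2, d1 + d2
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / v


class TestKaplanMeier:
    def test_all_censored_stays_at_one(self):
        km = km_estimate([1, 2, 3], [False, False, False])
        assert km.event_times.size == 0

    def test_no_censoring_is_empirical_survival(self):
        km = km_estimate([1, 2, 3, 4], [True, True, True, True])
        assert np.allclose(km.survival_probs, [0.75, 0.5, 0.25, 0.0])
        assert km.survival_at(2) == 0.5

    def test_hand_product_limit_with_censoring(self):
        # times 1, 2+, 3, 4: S(3) = (3/4) * (1/2) = 0.375
        km = km_estimate([1, 2, 3, 4], [True, False, True, True])
        assert km.survival_at(3) == pytest.approx(0.375)

    def test_censored_at_event_time_still_at_risk(self):
        # censoring at t=2 counts in the risk set of the t=2 event
        km = km_estimate([1, 2, 2, 4], [True, True, False, True])
        assert km.at_risk.tolist() == [4, 3, 1]

    def test_no_censoring_matches_empirical_everywhere(self, rng):
        t = rng.exponential(10, 50)
        km = km_estimate(t, np.ones(50, bool))
        for u in km.event_times:
            assert km.survival_at(u) == pytest.approx((t > u).mean(), abs=1e-12)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([0.0, 1.0], [True, True])


class TestLogrank:
    def test_identical_groups_give_null(self):
        t, e = [1, 2, 3, 4], [True, False, True, True]
        res = logrank_test(t, e, t, e)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_small_instance_matches_hand_tabulation(self):
        ta, ea = [1.0, 3.0, 5.0], [True, True, False]
        tb, eb = [2.0, 4.0, 6.0], [True, False, True]
        res = logrank_test(ta, ea, tb, eb)
        assert res.chi_square == pytest.approx(naive_logrank(ta, ea, tb, eb),
                                               abs=1e-12)

    def test_matches_naive_oracle_with_ties(self, rng):
        for _ in range(20):
            ta = rng.integers(1, 10, 15).astype(float)
            tb = rng.integers(1, 10, 12).astype(float)
            ea = rng.random(15) < 0.7
            eb = rng.random(12) < 0.7
            if ea.sum() + eb.sum() == 0:
                continue
            res = logrank_test(ta, ea, tb, eb)
            if res.defined:
                assert res.chi_square == pytest.approx(
                    naive_logrank(ta, ea, tb, eb), abs=1e-10)

    def test_symmetric_in_group_labels(self, rng):
        time, event, x = random_survival_fixture(rng)
        g = x > 0
        a = logrank_test(time[g], event[g], time[~g], event[~g])
        b = logrank_test(time[~g], event[~g], time[g], event[g])
        assert a.chi_square == pytest.approx(b.chi_square, abs=1e-12)

    def test_no_events_flagged_undefined(self):
        res = logrank_test([1, 2], [False, False], [3, 4], [False, False])
        assert not res.defined


class TestCox:
    def test_identical_groups_give_zero_beta(self):
        t = [1.0, 2.0, 5.0, 7.0] * 2
        e = [True, True, False, True] * 2
        x = [0.0] * 4 + [1.0] * 4
        fit = cox_univariate(t, e, x)
        assert fit.converged
        assert fit.beta == pytest.approx(0.0, abs=1e-6)
        assert fit.hazard_ratio == pytest.approx(np.exp(fit.beta))

    def test_score_test_equals_logrank_on_tiefree_binary(self, rng):
        for _ in range(10):
            time, event, x = random_survival_fixture(rng, n_max=80)
            g = (x > 0).astype(float)
            if np.ptp(g) == 0 or event.sum() < 2:
                continue
            lr = logrank_test(time[g == 0], event[g == 0],
                              time[g == 1], event[g == 1])
            score = cox_score_statistic(time, event, g, ties="breslow")
            assert score == pytest.approx(lr.chi_square, abs=1e-8)

    def test_recovers_planted_effect(self, rng):
        betas = []
        for _ in range(30):
            time, event, x = random_survival_fixture(rng, n_max=200, effect=0.7)
            betas.append(cox_univariate(time, event, x).beta)
        assert np.mean(betas) == pytest.approx(0.7, abs=0.15)

    def test_perfect_separation_flagged(self):
        # every event carries the larger covariate: likelihood is monotone
        t = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        e = [True, True, True, False, False, False]
        x = [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]
        fit = cox_univariate(t, e, x)
        assert not fit.converged
        assert fit.divergence_direction == 1

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            cox_univariate([1, 2, 3], [True, True, True], [1, 1, 1])

    def test_efron_and_breslow_agree_without_ties(self, rng):
        time, event, x = random_survival_fixture(rng, n_max=60)
        a = cox_univariate(time, event, x, ties="efron")
        b = cox_univariate(time, event, x, ties="breslow")
        assert a.beta == pytest.approx(b.beta, abs=1e-8)


class TestCutpoint:
    def test_ten_percent_rule_excludes_3_of_37(self, rng):
        scores = np.arange(1.0, 38.0)
        t = np.empty(37)
        e = np.zeros(37, bool)
        t[34:], e[34:] = [1.0, 2.0, 3.0], True
        t[:34] = rng.uniform(40, 100, 34)
        e[:34] = rng.random(34) < 0.4
        unconstrained = optimal_survival_cutpoint(scores, t, e, min_group_frac=0.0)
        assert unconstrained.n_high == 3
        assert not unconstrained.passes_constraint  # 3/37 < 10%
        constrained = optimal_survival_cutpoint(scores, t, e)
        assert constrained.threshold != unconstrained.threshold
        assert min(constrained.n_low, constrained.n_high) >= np.ceil(0.10 * 37)
        assert constrained.passes_constraint

    def test_group_sizes_partition_cohort(self, rng):
        time, event, x = random_survival_fixture(rng)
        res = optimal_survival_cutpoint(x, time, event)
        assert res.n_low + res.n_high == time.size

    def test_monotone_transform_leaves_p_invariant(self, rng):
        time, event, x = random_survival_fixture(rng, n_max=80)
        a = optimal_survival_cutpoint(x, time, event)
        b = optimal_survival_cutpoint(np.exp(x), time, event)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
        assert a.n_low == b.n_low

    def test_constant_scores_give_empty_result(self):
        assert optimal_survival_cutpoint([5.0] * 10, np.arange(1, 11),
                                         [True] * 10) is None


class TestPermutationAdjust:
    def test_off_switch_passes_raw_p_through(self, rng):
        time, event, x = random_survival_fixture(rng, n_max=60)
        raw = optimal_survival_cutpoint(x, time, event).p_value
        assert minp_permutation_adjust(x, time, event, 0, seed=1) == raw

    def test_extreme_rank_attains_lower_bound(self, rng):
        # strong planted split: observed min-p below every permuted one
        s = np.concatenate([np.zeros(20), np.ones(20)])
        t = np.concatenate([np.arange(1, 21) + 50.0, np.arange(1, 21) / 2.0])
        e = np.ones(40, bool)
        adj = minp_permutation_adjust(s, t, e, 199, seed=3)
        assert adj == pytest.approx(1 / 200)

    def test_null_adjusted_p_not_anticonservative(self, rng):
        ps = []
        for i in range(25):
            time, event, x = random_survival_fixture(rng, n_max=40)
            ps.append(minp_permutation_adjust(x, time, event, 100, seed=i))
        # under the null, adjusted p should not pile up near zero
        assert np.mean(np.array(ps) < 0.05) <= 0.2
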