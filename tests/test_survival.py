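"""Cox loss, concordance index, Kaplan–Meier, log-rank, and tercile
stratification — each against an independent oracle."""

import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.utils import concordance_index as ll_cindex
from scipy.stats import chi2

from omisurv.matrix import InvalidInputError
from omisurv.survival import (
    NonAdmissibleError,
    SurvivalData,
    concordance_index,
    cox_loss,
    cox_loss_grad,
    km_estimate,
    logrank_test,
    tercile_stratify,
)


def random_records(rng, n=50, censor=0.4):
    t = rng.exponential(100.0, n) + 1.0
    e = (rng.random(n) > censor).astype(int)
    if e.sum() == 0:
        e[0] = 1
    return SurvivalData(t, e)


def brute_force_cindex(scores, data):
    """O(n^2) double loop implementing the admissible-pair definition."""
    num = den = 0.0
    for i in range(len(data)):
        for j in range(len(data)):
            if data.time[i] < data.time[j] and data.event[i] == 1:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


def hand_logrank(a, b):
    """Observed-minus-expected tabulation over the distinct event times."""
    times = np.unique(np.concatenate([a.time[a.event == 1], b.time[b.event == 1]]))
    o_minus_e = var = 0.0
    for tau in times:
        n1 = (a.time >= tau).sum()
        n2 = (b.time >= tau).sum()
        d1 = ((a.time == tau) & (a.event == 1)).sum()
        d2 = ((b.time == tau) & (b.event == 1)).sum()
        n, d = n1 + n2, d1 + d2
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestCoxLoss:
    def test_single_event_equal_scores_gives_log3(self):
        data = SurvivalData([1.0, 2.0, 3.0], [1, 0, 0])
        assert cox_loss(np.zeros(3), data) == pytest.approx(np.log(3), abs=1e-9)

    def test_all_censored_is_non_admissible(self):
        data = SurvivalData([1.0, 2.0], [0, 0])
        with pytest.raises(NonAdmissibleError):
            cox_loss(np.array([0.5, 0.1]), data)

    def test_shift_invariance(self, rng):
        data = random_records(rng, 30)
        s = rng.normal(size=30)
        assert cox_loss(s, data) == pytest.approx(cox_loss(s + 17.3, data), abs=1e-10)

    def test_raising_an_event_score_lowers_the_loss(self, rng):
        data = random_records(rng, 25)
        s = rng.normal(size=25)
        i = int(np.flatnonzero(data.event == 1)[0])
        bumped = s.copy()
        bumped[i] += 1e-4
        assert cox_loss(bumped, data) < cox_loss(s, data)

    def test_gradient_matches_finite_differences(self, rng):
        data = random_records(rng, 20)
        s = rng.normal(size=20)
        loss, grad = cox_loss_grad(s, data)
        eps = 1e-6
        for i in range(0, 20, 5):
            sp, sm = s.copy(), s.copy()
            sp[i] += eps
            sm[i] -= eps
            num = (cox_loss(sp, data) - cox_loss(sm, data)) / (2 * eps)
            assert grad[i] == pytest.approx(num, abs=1e-7)

    def test_breslow_tied_event_times_share_risk_set(self):
        # two events tied at t=1 with a third sample at t=2, all scores 0:
        # each event contributes log(3) under Breslow
        data = SurvivalData([1.0, 1.0, 2.0], [1, 1, 0])
        assert cox_loss(np.zeros(3), data) == pytest.approx(np.log(3), abs=1e-12)


class TestConcordance:
    def test_perfect_reverse_ordering_scores_one(self):
        t = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        data = SurvivalData(t, np.ones(5, dtype=int))
        assert concordance_index(-t, data) == 1.0

    def test_all_tied_scores_give_half(self, rng):
        data = random_records(rng, 20)
        assert concordance_index(np.zeros(20), data) == 0.5

    def test_no_admissible_pairs_raises(self):
        data = SurvivalData([3.0, 2.0], [0, 0])
        with pytest.raises(NonAdmissibleError):
            concordance_index(np.array([1.0, 2.0]), data)

    def test_matches_brute_force_exactly_on_random_censored_data(self, rng):
        for _ in range(25):
            data = random_records(rng, 50)
            s = rng.normal(size=50)
            assert concordance_index(s, data) == brute_force_cindex(s, data)

    def test_agrees_with_lifelines_on_tie_free_data(self, rng):
        data = random_records(rng, 60)
        s = rng.normal(size=60)
        expected = ll_cindex(data.time, -s, data.event)
        assert concordance_index(s, data) == pytest.approx(expected, abs=1e-12)

    def test_complement_symmetry_without_score_ties(self, rng):
        data = random_records(rng, 40)
        s = rng.normal(size=40)
        assert concordance_index(s, data) == pytest.approx(
            1.0 - concordance_index(-s, data), abs=1e-12
        )


class TestKaplanMeier:
    def test_hand_computed_toy_curve(self):
        data = SurvivalData([1.0, 2.0, 3.0], [1, 0, 1])
        km = km_estimate(data)
        np.testing.assert_array_equal(km.event_times, [1.0, 3.0])
        np.testing.assert_allclose(km.survival, [2.0 / 3.0, 0.0])
        np.testing.assert_array_equal(km.at_risk, [3, 1])

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate(SurvivalData([1.0, 2.0, 3.0], [0, 0, 0]))
        assert km.event_times.size == 0

    def test_non_increasing_and_intervals_contain_estimate(self, rng):
        km = km_estimate(random_records(rng, 80))
        assert (np.diff(km.survival) <= 1e-12).all()
        assert (km.ci_low <= km.survival + 1e-12).all()
        assert (km.survival <= km.ci_high + 1e-12).all()
        assert (km.ci_low >= 0).all() and (km.ci_high <= 1).all()

    def test_point_estimates_agree_with_lifelines(self, rng):
        data = random_records(rng, 70)
        km = km_estimate(data)
        kmf = KaplanMeierFitter().fit(data.time, data.event)
        expected = kmf.survival_function_at_times(km.event_times).to_numpy()
        np.testing.assert_allclose(km.survival, expected, atol=1e-12)


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self, rng):
        a = random_records(rng, 30)
        stat, p = logrank_test(a, a)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_tabulation_on_toy_groups(self):
        a = SurvivalData([1.0, 2.0, 3.0], [1, 1, 1])
        b = SurvivalData([4.0, 5.0, 6.0], [1, 1, 1])
        stat, p = logrank_test(a, b)
        expected = hand_logrank(a, b)
        assert stat == pytest.approx(expected, rel=1e-9)
        assert p == pytest.approx(chi2.sf(expected, df=1), rel=1e-9)

    def test_matches_hand_tabulation_on_random_censored_groups(self, rng):
        a, b = random_records(rng, 40), random_records(rng, 35)
        stat, _ = logrank_test(a, b)
        assert stat == pytest.approx(hand_logrank(a, b), rel=1e-9)

    def test_symmetric_under_group_swap(self, rng):
        a, b = random_records(rng, 20), random_records(rng, 25)
        assert logrank_test(a, b)[0] == pytest.approx(logrank_test(b, a)[0])

    def test_no_events_raises(self):
        a = SurvivalData([1.0, 2.0], [0, 0])
        with pytest.raises(NonAdmissibleError):
            logrank_test(a, a)


class TestTercileStratify:
    def test_nine_distinct_scores_split_three_ways(self, rng):
        s = rng.permutation(9).astype(float)
        strata = tercile_stratify(s)
        for label in ("low", "intermediate", "high"):
            assert strata.mask(label).sum() == 3

    def test_cuts_are_the_33rd_and_66th_percentiles(self, rng):
        s = rng.normal(size=100)
        strata = tercile_stratify(s)
        assert strata.cut_low == np.percentile(s, 33)
        assert strata.cut_high == np.percentile(s, 66)

    def test_heavy_ties_match_sort_based_oracle(self, rng):
        s = np.concatenate([np.full(40, 1.0), rng.normal(5, 1, 60)])
        s = rng.permutation(s)
        strata = tercile_stratify(s)
        lo, hi = np.percentile(s, [33, 66])
        for val, lab in zip(s, strata.labels):
            expected = "low" if val <= lo else ("intermediate" if val <= hi else "high")
            assert lab == expected

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidInputError):
            tercile_stratify(np.array([1.0, 2.0]))
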