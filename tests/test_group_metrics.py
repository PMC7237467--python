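"""Cooperation statistics: success rates, ES, correlations, zeta."""

import math

import numpy as np
import pytest
from scipy.stats import pearsonr, spearmanr

from neurongame import (
    action_time_correlation,
    cooperation_measure,
    correct_response_rate,
    event_synchronization,
    pairwise_success,
    success_rate,
    synchronization_by_distance,
)
from neurongame.group_metrics import correlation_matrix, success_matrix

TWO_PI = 2 * math.pi


def _toy_walk():
    """4 decision points with target distances 100 -> 90 -> 95 -> 80."""
    target = np.zeros((3, 2))
    pos = np.array([[100.0, 0], [90.0, 0], [95.0, 0]])
    pos_next = np.array([[90.0, 0], [95.0, 0], [80.0, 0]])
    actions = np.ones((3, 2), dtype=int)
    return actions, pos, pos_next, target


class TestSuccessRate:
    def test_hand_counted_toy(self):
        a, p, pn, t = _toy_walk()
        assert success_rate(a, p, pn, t, 0.0) == pytest.approx(2 / 3)

    def test_idle_rows_excluded(self):
        a, p, pn, t = _toy_walk()
        a[1] = 0  # the failing step becomes a non-decision
        assert success_rate(a, p, pn, t, 0.0) == pytest.approx(1.0)

    def test_all_idle_is_undefined(self):
        a, p, pn, t = _toy_walk()
        assert math.isnan(success_rate(np.zeros_like(a), p, pn, t))

    def test_monotone_in_delta(self):
        a, p, pn, t = _toy_walk()
        vals = [success_rate(a, p, pn, t, d) for d in (0.0, 5.0, 10.0, 25.0)]
        assert all(x >= y for x, y in zip(vals, vals[1:]))

    def test_improvement_bound(self):
        # no 8-player group of 10 px steps can improve by more than 80 px
        a, p, pn, t = _toy_walk()
        assert success_rate(a, p, pn, t, 81.0) == 0.0

    def test_matches_brute_force_oracle(self, rng):
        """Exact (integer-count) agreement with a literal loop over rows."""
        for _ in range(10):
            n, k = 40, 4
            a = (rng.random((n, k)) < 0.4).astype(int)
            pos = np.cumsum(rng.normal(0, 5, (n + 1, 2)), axis=0) + 200
            target = np.full((n, 2), 150.0)
            delta = rng.uniform(0, 3)
            num = den = 0
            for t in range(n):
                if a[t].sum() >= 1:
                    den += 1
                    d0 = np.hypot(*(target[t] - pos[t]))
                    d1 = np.hypot(*(target[t] - pos[t + 1]))
                    if d0 - d1 > delta:
                        num += 1
            expected = num / den if den else float("nan")
            got = success_rate(a, pos[:-1], pos[1:], target, delta)
            assert got == pytest.approx(expected)


class TestPairwiseSuccess:
    def test_diagonal_is_own_conditional_success(self, rng):
        a, p, pn, t = _toy_walk()
        assert pairwise_success(a, p, pn, t, 0.0, 0, 0) == pytest.approx(2 / 3)

    def test_co_active_only_on_good_steps(self):
        a, p, pn, t = _toy_walk()
        a[1, 1] = 0  # pair (0,1) co-active only on the two improving steps
        assert pairwise_success(a, p, pn, t, 0.0, 0, 1) == pytest.approx(1.0)

    def test_never_co_active_is_undefined(self):
        a, p, pn, t = _toy_walk()
        a[:, 1] = 0
        assert math.isnan(pairwise_success(a, p, pn, t, 0.0, 0, 1))

    def test_matrix_matches_scalar(self, rng):
        n, k = 60, 4
        a = (rng.random((n, k)) < 0.5).astype(int)
        pos = np.cumsum(rng.normal(0, 5, (n + 1, 2)), axis=0)
        target = np.full((n, 2), 30.0)
        mat = success_matrix(a, pos[:-1], pos[1:], target)
        for i in range(k):
            for j in range(k):
                expected = pairwise_success(a, pos[:-1], pos[1:], target, 0.0, i, j)
                if math.isnan(expected):
                    assert math.isnan(mat[i, j])
                else:
                    assert mat[i, j] == pytest.approx(expected)


class TestCorrectResponse:
    def test_helpful_direction_counts(self):
        # target far to the east; player 0 points east, player 1 west
        n = 5
        pos = np.tile([0.0, 0.0], (n, 1))
        target = np.tile([1000.0, 0.0], (n, 1))
        a = np.ones((n, 2), dtype=int)
        assert correct_response_rate(a, pos, target, 0.0, 0) == 1.0
        assert correct_response_rate(a, pos, target, math.pi, 1) == 0.0

    def test_hand_mixed_example(self):
        pos = np.array([[0.0, 0], [500.0, 0], [990.0, 0], [995.0, 0], [100.0, 0]])
        target = np.tile([1000.0, 0.0], (5, 1))
        a = np.ones((5, 1), dtype=int)
        # due-east steps help except when overshooting from 995 (dist 5 -> 5)
        assert correct_response_rate(a, pos, target, 0.0, 0) == pytest.approx(4 / 5)

    def test_no_spikes_undefined(self):
        pos = np.zeros((3, 2))
        target = np.tile([10.0, 0.0], (3, 1))
        assert math.isnan(correct_response_rate(np.zeros((3, 1), int), pos, target, 0.0, 0))


def _es_brute_force(ti, tj):
    """Literal double-loop evaluation of the synchronization definition."""
    def half_min(ts, k):
        cands = []
        if k + 1 < len(ts):
            cands.append(ts[k + 1] - ts[k])
        if k - 1 >= 0:
            cands.append(ts[k] - ts[k - 1])
        return 0.5 * min(cands) if cands else math.inf

    total = 0.0
    for k in range(len(ti)):
        for l in range(len(tj)):
            tau = min(half_min(ti, k), half_min(tj, l))
            for x, y in ((ti[k], tj[l]), (tj[l], ti[k])):
                if x == y:
                    total += 0.5
                elif 0 < x - y <= tau:
                    total += 1.0
    return total / math.sqrt(len(ti) * len(tj))


class TestEventSynchronization:
    def test_identical_trains(self):
        t = [3.0, 17.0, 40.0, 41.0]
        assert event_synchronization(t, t) == pytest.approx(1.0)

    def test_distant_trains(self):
        assert event_synchronization([0, 10, 20], [1000, 1010, 1020]) == 0.0

    def test_listed_pair_oracle(self):
        ti, tj = [10.0, 20.0, 30.0], [12.0, 40.0]
        expected = _es_brute_force(ti, tj)
        assert expected == pytest.approx(1 / math.sqrt(6))
        assert event_synchronization(ti, tj) == pytest.approx(expected)

    def test_matches_brute_force_on_random_trains(self, rng):
        for _ in range(20):
            ti = np.unique(rng.integers(0, 60, size=rng.integers(1, 15)))
            tj = np.unique(rng.integers(0, 60, size=rng.integers(1, 15)))
            got = event_synchronization(ti, tj)
            assert got == pytest.approx(_es_brute_force(list(ti), list(tj)))
            assert 0.0 <= got <= 1.0 + 1e-9
            assert got == pytest.approx(event_synchronization(tj, ti))  # symmetry

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            event_synchronization([], [1.0])


class TestActionTimeCorrelation:
    def test_identical_columns(self):
        a = np.array([[1, 1], [0, 0], [1, 1], [0, 0], [1, 1]])
        assert action_time_correlation(a, 0, 1) == pytest.approx(1.0)

    def test_complementary_columns(self):
        a = np.array([[1, 0], [0, 1], [1, 0], [0, 1]])
        assert action_time_correlation(a, 0, 1) == pytest.approx(-1.0)

    def test_constant_column_undefined(self):
        a = np.array([[1, 1], [1, 0], [1, 1]])
        assert math.isnan(action_time_correlation(a, 0, 1))

    def test_independent_columns_near_zero(self, rng):
        a = (rng.random((10_000, 2)) < 0.4).astype(int)
        assert abs(action_time_correlation(a, 0, 1)) < 0.05

    def test_equals_pearson_and_spearman_on_binary(self, rng):
        """On binary columns the printed product-moment formula, Pearson and
        Spearman all coincide (phi coefficient)."""
        a = (rng.random((300, 2)) < 0.5).astype(int)
        ours = action_time_correlation(a, 0, 1)
        assert ours == pytest.approx(pearsonr(a[:, 0], a[:, 1]).statistic)
        assert ours == pytest.approx(spearmanr(a[:, 0], a[:, 1]).statistic)


class TestCooperationMeasure:
    def _mats(self, rng):
        c = rng.uniform(-0.2, 0.4, (8, 8))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        return c

    def test_constant_success_gives_zero(self, rng):
        c = self._mats(rng)
        s = np.full((8, 8), 0.7)
        assert cooperation_measure(c, s) == pytest.approx(0.0, abs=1e-12)

    def test_self_covariance_is_variance(self, rng):
        c = self._mats(rng)
        z = cooperation_measure(c, c)
        iu = np.triu_indices(8, 1)
        assert z == pytest.approx(np.var(c[iu], ddof=1))
        assert z >= 0.0

    def test_anti_ordering_is_negative(self, rng):
        c = self._mats(rng)
        assert cooperation_measure(c, 1.0 - c) < 0.0

    def test_shift_invariance(self, rng):
        c = self._mats(rng)
        s = self._mats(rng)
        z1 = cooperation_measure(c, s)
        z2 = cooperation_measure(c, s + 0.137)
        assert z1 == pytest.approx(z2)

    def test_undefined_pairs_reported(self, rng):
        c = self._mats(rng)
        s = self._mats(rng)
        s[2, 5] = s[5, 2] = np.nan
        with pytest.raises(ValueError, match=r"\(2, 5\)"):
            cooperation_measure(c, s)


class TestSynchronizationProfile:
    def test_flat_es_gives_flat_profile(self):
        es = np.full((8, 8), 0.5)
        mu = np.arange(8) * math.pi / 4
        prof = synchronization_by_distance(es, mu)
        assert set(np.round(list(prof), 6)) == set(
            np.round([-3 * math.pi / 4, -math.pi / 2, -math.pi / 4,
                      math.pi / 4, math.pi / 2, 3 * math.pi / 4, math.pi], 6))
        assert all(v == pytest.approx(0.5) for v in prof.values())

    def test_distance_coded_es_decreases(self):
        mu = np.arange(8) * math.pi / 4
        es = np.empty((8, 8))
        for i in range(8):
            for j in range(8):
                d = abs((mu[j] - mu[i] + math.pi) % TWO_PI - math.pi)
                es[i, j] = 1.0 - d / math.pi
        prof = synchronization_by_distance(es, mu)
        by_abs = {}
        for k, v in prof.items():
            by_abs.setdefault(round(abs(k), 6), []).append(v)
        keys = sorted(by_abs)
        means = [np.mean(by_abs[k]) for k in keys]
        assert all(a > b for a, b in zip(means, means[1:]))
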