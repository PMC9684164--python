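import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zknock import feature_stats, knockoff_threshold, q_values, select


def brute_force_threshold(kappa, tau, q, M):
    """Exhaustive scan over every positive candidate threshold."""
    best = np.inf
    for t in sorted(set(tau[tau > 0])):
        num = (1.0 + np.sum((kappa >= 1) & (tau >= t))) / M
        den = np.sum((kappa == 0) & (tau >= t))
        if den > 0 and num / den <= q:
            best = min(best, t)
    return best


def brute_force_qvalues(kappa, tau, M):
    q = np.ones(len(kappa))
    for j in range(len(kappa)):
        if kappa[j] != 0:
            continue
        best = np.inf
        for t in sorted(set(tau[tau > 0])):
            if t > tau[j]:
                continue
            num = (1.0 + np.sum((kappa >= 1) & (tau >= t))) / M
            den = np.sum((kappa == 0) & (tau >= t))
            if den > 0:
                best = min(best, num / den)
        q[j] = min(best, 1.0)
    return q


class TestFeatureStats:
    def test_original_wins(self):
        # T = 9 vs knockoff scores (1, 0, 4, 1, 0)
        z = np.array([3.0])
        zk = np.sqrt(np.array([[1.0, 0.0, 4.0, 1.0, 0.0]]))
        s = feature_stats(z, zk)
        assert s.kappa[0] == 0
        assert s.tau[0] == pytest.approx(9 - np.median([4, 1, 1, 0, 0]))
        assert s.W[0] == pytest.approx(8.0)

    def test_knockoff_wins(self):
        # T = 2 vs knockoff scores (5, 0, 1, 1, 0): copy 1 takes the max
        z = np.array([np.sqrt(2.0)])
        zk = np.sqrt(np.array([[5.0, 0.0, 1.0, 1.0, 0.0]]))
        s = feature_stats(z, zk)
        assert s.kappa[0] == 1
        assert s.tau[0] == pytest.approx(5 - np.median([2, 1, 1, 0, 0]))
        assert s.W[0] == 0.0

    def test_exact_ties_uniform_kappa(self):
        """Degenerate all-equal scores: kappa uniform over {0..M} across seeds."""
        M = 5
        z = np.ones(1)
        zk = np.ones((1, M))
        counts = np.zeros(M + 1)
        n = 3000
        for seed in range(n):
            s = feature_stats(z, zk, tie_seed=seed)
            counts[s.kappa[0]] += 1
        expected = n / (M + 1)
        assert np.all(np.abs(counts - expected) < 5 * np.sqrt(expected))

    def test_w_is_tau_masked_by_kappa(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal(200)
        zk = rng.standard_normal((200, 5))
        s = feature_stats(z, zk, tie_seed=1)
        np.testing.assert_array_equal(s.W, s.tau * (s.kappa == 0))
        np.testing.assert_array_equal(s.T, z**2)
        assert np.all(s.tau >= 0)

    def test_rejects_nan_and_empty_knockoffs(self):
        with pytest.raises(ValueError, match="indices \\[1\\]"):
            feature_stats(np.array([1.0, np.nan]), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            feature_stats(np.array([1.0]), np.zeros((1, 0)))


class TestThreshold:
    def test_worked_example_inclusive_selection(self):
        kappa = np.array([0, 0, 0, 1, 0])
        tau = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        # at t=3: (1 + 0)/1 / 3 = 1/3 <= 0.35
        assert knockoff_threshold(kappa, tau, 0.35, M=1) == 3.0
        assert knockoff_threshold(kappa, tau, 0.2, M=1) == np.inf

    def test_detection_threshold_arithmetic(self):
        """All-original case, M=5: need >= 1/(M q) = 2 survivors at q = 0.1."""
        # a single signal cannot clear the filter: (1/5)/1 = 0.2 > 0.1
        assert knockoff_threshold(np.zeros(1, int), np.array([9.0]), 0.1, M=5) == np.inf
        # two signals can: (1/5)/2 = 0.1 <= 0.1, threshold = smaller tau
        thr = knockoff_threshold(np.zeros(2, int), np.array([9.0, 4.0]), 0.1, M=5)
        assert thr == 4.0
        # with many survivors the threshold is the smallest positive tau
        rng = np.random.default_rng(0)
        tau = rng.random(100) + 0.01
        thr = knockoff_threshold(np.zeros(100, int), tau, 0.1, M=5)
        assert thr == tau.min()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            knockoff_threshold(np.array([]), np.array([]), 0.1, 1)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.integers(5, 51)
        M = int(rng.choice([1, 3, 5]))
        kappa = rng.integers(0, M + 1, size=p)
        tau = np.round(rng.exponential(2.0, size=p), 2)
        for q in (0.05, 0.1, 0.2, 0.35, 0.5):
            assert knockoff_threshold(kappa, tau, q, M) == brute_force_threshold(kappa, tau, q, M)


class TestQValues:
    def test_worked_example(self):
        kappa = np.array([0, 0, 0, 1, 0])
        tau = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        np.testing.assert_allclose(
            q_values(kappa, tau, M=1), [1 / 3, 1 / 3, 1 / 3, 1.0, 1 / 2]
        )

    def test_knockoff_winner_gets_q_one(self):
        q = q_values(np.array([2, 0]), np.array([9.0, 1.0]), M=5)
        assert q[0] == 1.0

    def test_single_original_variant(self):
        np.testing.assert_allclose(q_values(np.array([0]), np.array([4.0]), M=5), [0.2])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        p = rng.integers(5, 51)
        M = int(rng.choice([1, 3, 5]))
        kappa = rng.integers(0, M + 1, size=p)
        tau = np.round(rng.exponential(2.0, size=p), 2)
        np.testing.assert_allclose(q_values(kappa, tau, M), brute_force_qvalues(kappa, tau, M))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_threshold_qvalue_duality(self, seed):
        """{q <= alpha} equals selection at threshold(alpha) on an alpha grid."""
        rng = np.random.default_rng(seed)
        p = rng.integers(3, 40)
        M = int(rng.choice([1, 5]))
        kappa = rng.integers(0, M + 1, size=p)
        tau = np.round(rng.exponential(2.0, size=p), 1)
        q = q_values(kappa, tau, M)
        for alpha in np.arange(0.01, 0.51, 0.07):
            thr = knockoff_threshold(kappa, tau, alpha, M)
            by_thr = (kappa == 0) & (tau >= thr)
            np.testing.assert_array_equal(q <= alpha, by_thr)


class TestSelect:
    def test_packages_threshold_and_set(self):
        # reproduces kappa=(0,0,0,1,0), tau=(5,4,3,2,1) at M=1
        z = np.sqrt(np.array([5.0, 4.0, 3.0, 0.5, 1.0]))
        zk = np.sqrt(np.array([[0.0], [0.0], [0.0], [2.5], [0.0]]))
        s = feature_stats(z, zk)
        res = select(s, 0.35)
        np.testing.assert_array_equal(res.selected, [0, 1, 2])
        assert np.all(res.qvalue[res.selected] <= 0.35)

    def test_empty_statistics_select_nothing(self):
        s = feature_stats(np.zeros(4), np.zeros((4, 5)), tie_seed=0)
        res = select(s, 0.1)
        assert res.selected.size == 0
        assert res.threshold == np.inf

    def test_pooled_blocks_equal_concatenated(self):
        """The filter over two blocks' pooled stats == one concatenated block."""
        rng = np.random.default_rng(9)
        z1, z2 = rng.standard_normal(30), rng.standard_normal(20)
        z1[0] = z2[0] = 5.0
        zk1, zk2 = rng.standard_normal((30, 5)), rng.standard_normal((20, 5))
        pooled = feature_stats(np.concatenate([z1, z2]), np.vstack([zk1, zk2]), tie_seed=4)
        res = select(pooled, 0.2)
        # same stats re-derived from the concatenation directly
        again = select(feature_stats(np.concatenate([z1, z2]), np.vstack([zk1, zk2]), tie_seed=4), 0.2)
        np.testing.assert_array_equal(res.selected, again.selected)
        assert res.threshold == again.threshold


def test_null_kappa_symmetry(sigma_ar1):
    """For null z exchangeable with its knockoffs, kappa is uniform on {0..M}."""
    from zknock import build_knockoff_model

    M = 5
    m = build_knockoff_model(sigma_ar1, M=M)
    p = m.p
    rng = np.random.default_rng(17)
    L = np.linalg.cholesky(sigma_ar1.R)
    counts = np.zeros(M + 1)
    n = 400
    for i in range(n):
        z = L @ rng.standard_normal(p)
        eps = m.V_factor @ rng.standard_normal(p * M)
        zk = (m.P @ z + eps).reshape(M, p).T
        s = feature_stats(z, zk, tie_seed=i)
        for k in range(M + 1):
            counts[k] += np.sum(s.kappa == k)
    total = counts.sum()
    freq = counts / total
    assert np.all(np.abs(freq - 1 / (M + 1)) < 4 * np.sqrt((1 / 6) * (5 / 6) / total) + 0.01)
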