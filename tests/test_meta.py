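import numpy as np
import pytest

from zknock import (
    StudyPanel,
    build_knockoff_model,
    effective_cc_n,
    effective_size_and_gamma,
    estimate_study_correlation,
    meta_knockoff_z,
    meta_z,
    optimal_weights,
    sample_knockoff_z,
    size_weights,
)


@pytest.fixture
def ar1_model(sigma_ar1):
    return build_knockoff_model(sigma_ar1, M=5)


def _null_panel(sigma, n_variants, K, rng, reps=1):
    """Stack independent null Z-draws from N(0, Sigma) into a panel."""
    L = np.linalg.cholesky(sigma.R)
    p = sigma.p
    blocks = [L @ rng.standard_normal((p, K)) for _ in range(reps)]
    return np.vstack(blocks)


class TestStudyCorrelation:
    def test_identical_studies_give_unit_correlation(self, sigma_ar1, ar1_model):
        rng = np.random.default_rng(0)
        z = _null_panel(sigma_ar1, 20, 1, rng)[:, 0]
        panel = StudyPanel(Z=np.column_stack([z, z]), n=np.array([100.0, 100.0]))
        corS = estimate_study_correlation(panel, ar1_model, min_shared=5)
        assert corS[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_independent_studies_near_zero(self, sigma_ar1, ar1_model):
        rng = np.random.default_rng(1)
        reps = 40
        ests = []
        for _ in range(reps):
            Z = np.hstack([
                _null_panel(sigma_ar1, 20, 1, rng),
                _null_panel(sigma_ar1, 20, 1, rng),
            ])
            panel = StudyPanel(Z=Z, n=np.array([100.0, 100.0]))
            ests.append(
                estimate_study_correlation(panel, ar1_model, min_shared=5)[0, 1]
            )
        se = np.std(ests, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(ests)) < 3 * se + 0.02

    def test_too_few_shared_nulls_rejected(self, sigma_ar1, ar1_model):
        rng = np.random.default_rng(2)
        Z = _null_panel(sigma_ar1, 20, 2, rng)
        panel = StudyPanel(Z=Z, n=np.array([100.0, 100.0]))
        with pytest.raises(ValueError, match="0 and 1"):
            estimate_study_correlation(panel, ar1_model, min_shared=100)


class TestWeights:
    def test_two_independent_equal_studies_closed_form(self):
        n = 400.0
        w = optimal_weights(np.eye(2), np.array([n, n]))
        np.testing.assert_allclose(w, 1.0 / (2.0 * np.sqrt(n)), atol=1e-8)

    def test_single_study_constraint_only(self):
        w = optimal_weights(np.eye(1), np.array([900.0]))
        np.testing.assert_allclose(w, 1.0 / 30.0, atol=1e-10)

    def test_duplicated_studies_symmetric_tie_break(self):
        w = opt = optimal_weights(np.ones((2, 2)), np.array([100.0, 100.0]))
        np.testing.assert_allclose(w[0], w[1], atol=1e-6)
        np.testing.assert_allclose(w @ np.sqrt([100.0, 100.0]), 1.0, atol=1e-10)

    def test_overlap_downweights_the_redundant_study(self):
        corS = np.array([[1.0, 0.8, 0.0], [0.8, 1.0, 0.0], [0.0, 0.0, 1.0]])
        n = np.array([1000.0, 1000.0, 1000.0])
        w = optimal_weights(corS, n)
        assert w[2] > w[0]  # the independent study carries more weight
        # objective no worse than rescaled size weights
        w_size = size_weights(n) / (size_weights(n) @ np.sqrt(n))
        assert w @ corS @ w <= w_size @ corS @ w_size + 1e-10

    def test_case_control_effective_size(self):
        np.testing.assert_allclose(
            effective_cc_n(np.array([5000.0]), np.array([5000.0])), 10000.0
        )
        # imbalance shrinks the effective size below the total
        assert effective_cc_n(np.array([1000.0]), np.array([9000.0]))[0] < 10000.0


class TestGamma:
    def test_independent_studies_gamma_one(self):
        mw = effective_size_and_gamma(np.eye(3), np.array([50.0, 500.0, 7.0]))
        assert mw.gamma == 1.0
        assert mw.N_eff == pytest.approx(557.0)

    def test_two_identical_studies(self):
        mw = effective_size_and_gamma(np.ones((2, 2)), np.array([300.0, 300.0]))
        assert mw.N_eff == pytest.approx(300.0)  # N/K
        assert mw.gamma == pytest.approx(np.sqrt(1 + 2 - 0.5))

    def test_optimal_scheme_identity_also_gamma_one(self):
        n = np.array([100.0, 400.0])
        w = optimal_weights(np.eye(2), n)
        mw = effective_size_and_gamma(np.eye(2), n, w=w, scheme="optimal")
        assert mw.gamma == pytest.approx(1.0, abs=1e-6)

    def test_noisy_neff_above_n_clipped(self):
        corS = np.array([[1.0, -0.2], [-0.2, 1.0]])  # estimation noise
        with pytest.warns(UserWarning, match="clipping"):
            mw = effective_size_and_gamma(corS, np.array([100.0, 100.0]))
        assert mw.gamma == 1.0
        assert mw.N_eff == pytest.approx(200.0)


class TestMetaZ:
    def test_missing_variant_drops_study_contribution(self):
        Z = np.array([[1.0, 2.0], [3.0, 4.0]])
        mask = np.array([[True, False], [True, True]])
        panel = StudyPanel(Z=Z, n=np.array([100.0, 100.0]), mask=mask)
        mw = effective_size_and_gamma(np.eye(2), panel.n)
        zm = meta_z(panel, mw)
        w = mw.w
        np.testing.assert_allclose(zm, [w[0] * 1.0, w[0] * 3.0 + w[1] * 4.0])

    def test_two_identical_studies_scale_by_sqrt2(self):
        z = np.array([1.0, -2.0, 0.5])
        panel = StudyPanel(Z=np.column_stack([z, z]), n=np.array([100.0, 100.0]))
        mw = effective_size_and_gamma(np.eye(2), panel.n)
        np.testing.assert_allclose(meta_z(panel, mw), np.sqrt(2) * z, atol=1e-12)

    def test_masking_touches_only_the_masked_row(self, ar1_model):
        rng = np.random.default_rng(3)
        Z = rng.standard_normal((20, 2))
        n = np.array([100.0, 100.0])
        mw = effective_size_and_gamma(np.eye(2), n)
        full = StudyPanel(Z=Z, n=n)
        mask = np.ones((20, 2), dtype=bool)
        mask[7, 1] = False
        part = StudyPanel(Z=Z, n=n, mask=mask)
        zm_full, zm_part = meta_z(full, mw), meta_z(part, mw)
        changed = np.flatnonzero(zm_full != zm_part)
        np.testing.assert_array_equal(changed, [7])
        # knockoff rows may change wherever the projection couples to the
        # masked variant (the zeroed Z feeds P); outside that LD
        # neighborhood the knockoff Z is untouched
        zt_full = meta_knockoff_z(full, mw, ar1_model, seed=5)
        zt_part = meta_knockoff_z(part, mw, ar1_model, seed=5)
        changed_rows = np.flatnonzero(np.any(zt_full != zt_part, axis=1))
        coupled = np.flatnonzero(np.abs(ar1_model.P[:20, 7]) > 1e-12)
        assert 7 in changed_rows
        assert set(changed_rows) <= set(coupled) | {7}


class TestMetaKnockoffZ:
    def test_single_study_reduces_to_plain_sampling(self, ar1_model):
        rng = np.random.default_rng(4)
        z = rng.standard_normal(20)
        panel = StudyPanel(Z=z[:, None], n=np.array([100.0]))
        mw = effective_size_and_gamma(np.eye(1), panel.n)
        assert mw.gamma == 1.0
        zt = meta_knockoff_z(panel, mw, ar1_model, seed=11)
        direct = sample_knockoff_z(ar1_model, mw.w[0] * z, gamma=1.0, seed=11)
        np.testing.assert_allclose(zt, direct.z_knock, atol=1e-12)

    def test_seeded_determinism(self, ar1_model):
        rng = np.random.default_rng(5)
        Z = rng.standard_normal((20, 2))
        panel = StudyPanel(Z=Z, n=np.array([100.0, 100.0]))
        mw = effective_size_and_gamma(np.eye(2), panel.n)
        a = meta_knockoff_z(panel, mw, ar1_model, seed=7)
        b = meta_knockoff_z(panel, mw, ar1_model, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_independent_meta_matches_pooled_null_covariance(self, sigma_ar1, ar1_model):
        """Meta of two independent equal studies has the same null (Z, Z~)
        second moments as a single study (exchangeable block form)."""
        rng = np.random.default_rng(6)
        p, M, n_draws = 20, 5, 4000
        L = np.linalg.cholesky(sigma_ar1.R)
        n = np.array([100.0, 100.0])
        mw = effective_size_and_gamma(np.eye(2), n)
        zs, zts = [], []
        for _ in range(n_draws):
            # independent studies at fixed total N: each Z_k ~ N(0, Sigma)
            Z = L @ rng.standard_normal((p, 2))
            panel = StudyPanel(Z=Z, n=n)
            zs.append(meta_z(panel, mw))
            zts.append(meta_knockoff_z(panel, mw, ar1_model,
                                       seed=int(rng.integers(2**31))))
        zm = np.asarray(zs)
        zt1 = np.asarray([t[:, 0] for t in zts])
        # var(Z_meta) = Sigma, cov(Z_meta, Z~_meta) = Sigma - D
        emp_zz = zm.T @ zm / n_draws
        emp_zt = zm.T @ zt1 / n_draws
        se = 3.0 / np.sqrt(n_draws)
        assert np.abs(emp_zz - sigma_ar1.R).max() < 4 * se
        assert np.abs(emp_zt - (sigma_ar1.R - np.diag(ar1_model.s))).max() < 4 * se

    def test_heterogeneous_groups_need_their_models(self, ar1_model):
        panel = StudyPanel(
            Z=np.zeros((20, 2)), n=np.array([10.0, 10.0]), group=np.array([0, 1])
        )
        mw = effective_size_and_gamma(np.eye(2), panel.n)
        with pytest.raises(ValueError, match="group"):
            meta_knockoff_z(panel, mw, {0: ar1_model}, seed=0)

    def test_heterogeneous_combination_runs_and_is_seeded(self, sigma_ar1):
        m0 = build_knockoff_model(sigma_ar1, M=3)
        from zknock import psd_repair

        sigma_b = psd_repair(0.3 ** np.abs(np.subtract.outer(range(20), range(20))))
        m1 = build_knockoff_model(sigma_b, M=3)
        rng = np.random.default_rng(8)
        panel = StudyPanel(
            Z=rng.standard_normal((20, 2)), n=np.array([100.0, 300.0]),
            group=np.array([0, 1]),
        )
        mw = effective_size_and_gamma(np.eye(2), panel.n)
        a = meta_knockoff_z(panel, mw, {0: m0, 1: m1}, seed=3)
        b = meta_knockoff_z(panel, mw, {0: m0, 1: m1}, seed=3)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (20, 3)
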