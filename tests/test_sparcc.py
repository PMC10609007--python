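"""SparCC estimator: primitives, closed-form identities, recovery behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sparccnet as sn
from sparccnet.sparcc import (
    LogRatioVariances,
    correlations_from_basis,
    dirichlet_fractions,
    estimate_basis_variances,
    logratio_variance_matrix,
    ml_fractions,
    sparcc_single_pass,
)


def forward_t(omega: np.ndarray, rho: np.ndarray) -> LogRatioVariances:
    """Build the exact log-ratio variance matrix implied by (omega, rho)."""
    s = np.sqrt(np.outer(omega, omega))
    t = omega[:, None] + omega[None, :] - 2.0 * rho * s
    np.fill_diagonal(t, 0.0)
    return LogRatioVariances(t=t, n=1000)


class TestDirichletFractions:
    def test_uniform_prior_centered(self):
        rng = np.random.default_rng(0)
        draws = np.array([dirichlet_fractions([0, 0], rng) for _ in range(10_000)])
        assert abs(draws[:, 0].mean() - 0.5) < 0.02  # Dirichlet(1,1) mean

    def test_support(self):
        rng = np.random.default_rng(1)
        f = dirichlet_fractions([3, 0, 7], rng)
        assert f.sum() == pytest.approx(1.0) and np.all(f > 0)

    def test_dominant_count_dominates(self):
        # Beta(1e6+1, 1): essentially all mass above 0.99
        rng = np.random.default_rng(2)
        firsts = [dirichlet_fractions([10**6, 0], rng)[0] for _ in range(100)]
        assert all(f > 0.99 for f in firsts)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            dirichlet_fractions([3.0, -1.0], 0)


class TestLogratioVariance:
    def test_proportional_pair_has_zero_variance(self):
        x = np.random.default_rng(3).uniform(0.1, 1, size=(1, 5))
        frac = np.vstack([2 * x, x, np.ones((1, 5))])
        frac = frac / frac.sum(axis=0)
        t = logratio_variance_matrix(frac)
        assert t.t[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_identical_samples_zero_matrix(self):
        frac = np.tile(np.array([[0.2], [0.3], [0.5]]), (1, 4))
        t = logratio_variance_matrix(frac)
        np.testing.assert_allclose(t.t, 0.0, atol=1e-12)

    def test_matches_direct_two_pass_variance(self):
        rng = np.random.default_rng(4)
        frac = rng.uniform(0.01, 1.0, size=(3, 4))
        frac /= frac.sum(axis=0)
        t = logratio_variance_matrix(frac)
        for i in range(3):
            for j in range(3):
                lr = np.log(frac[i] / frac[j])
                assert t.t[i, j] == pytest.approx(np.var(lr, ddof=1), abs=1e-12)

    def test_rejects_nonpositive_fractions(self):
        with pytest.raises(ValueError):
            logratio_variance_matrix(np.array([[0.5, 0.0], [0.5, 1.0]]))


class TestBasisVariances:
    def test_symmetric_case_forced(self):
        t = LogRatioVariances(t=np.full((4, 4), 2.0) - 2.0 * np.eye(4), n=10)
        omega, floored = estimate_basis_variances(t)
        np.testing.assert_allclose(omega, 1.0, atol=1e-12)
        assert not floored

    def test_recovers_planted_variances_under_independence(self):
        omega = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        t = forward_t(omega, np.zeros((5, 5)))
        est, _ = estimate_basis_variances(t)
        np.testing.assert_allclose(est, omega, atol=1e-9)

    def test_underdetermined_below_four_taxa(self):
        t = LogRatioVariances(t=np.zeros((3, 3)), n=10)
        with pytest.raises(ValueError, match="at least 4"):
            estimate_basis_variances(t)


class TestCorrelationIdentity:
    @pytest.mark.parametrize(
        "oi,oj,tij,expected",
        [(1, 1, 2, 0.0), (1, 1, 0, 1.0), (1, 4, 1, 1.0)],
    )
    def test_formula_arithmetic(self, oi, oj, tij, expected):
        omega = np.array([oi, oj, 1.0, 1.0])
        # fill the other pairs with their independence values so only the
        # (0, 1) entry carries signal and nothing clips
        t = omega[:, None] + omega[None, :]
        np.fill_diagonal(t, 0.0)
        t[0, 1] = t[1, 0] = tij
        rho, n_clip = correlations_from_basis(LogRatioVariances(t=t, n=10), omega)
        assert rho[0, 1] == pytest.approx(expected)
        assert n_clip == 0

    def test_inversion_exact_with_true_variances(self):
        # the correlation identity inverts the forward construction exactly
        rng = np.random.default_rng(5)
        omega = rng.uniform(0.5, 2.0, size=6)
        rho = np.eye(6)
        rho[0, 1] = rho[1, 0] = 0.4
        rho[2, 3] = rho[3, 2] = -0.3
        t = forward_t(omega, rho)
        back, _ = correlations_from_basis(t, omega)
        np.testing.assert_allclose(back, rho, atol=1e-9)


class TestSinglePass:
    def _fractions_with_pair(self, rho_pair=0.95, D=8, n=300, seed=6):
        cov = np.eye(D)
        cov[0, 1] = cov[1, 0] = rho_pair
        rng = np.random.default_rng(seed)
        z = rng.multivariate_normal(np.zeros(D), cov, size=n).T
        w = np.exp(z)
        return w / w.sum(axis=0)

    def test_planted_strong_pair_excluded_first(self):
        frac = self._fractions_with_pair()
        _, _, excluded, _, _ = sparcc_single_pass(frac, exclusion_threshold=0.1)
        assert excluded[0] == (0, 1)

    def test_unreachable_threshold_never_excludes(self):
        frac = self._fractions_with_pair()
        _, _, excluded, _, _ = sparcc_single_pass(frac, exclusion_threshold=1.0)
        assert excluded == []

    def test_exclusion_budget_degeneracy_error(self):
        frac = self._fractions_with_pair()
        with pytest.raises(ValueError, match="degeneracy"):
            sparcc_single_pass(frac, max_exclusions=1000)

    def test_null_triggers_few_exclusions_and_stays_calibrated(self):
        # independent taxa: sampling noise alone crosses the 0.1 threshold for
        # a handful of pairs at n=500, but the estimate stays calibrated
        for seed in range(5):
            b = sn.plant_correlation_network(20, 1, hub_count=0, within_rho=0.0, seed=seed)
            table, _ = sn.simulate_count_table(b, n_per_group=500, depth=50_000, seed=100 + seed)
            frac = ml_fractions(table.counts.astype(float))
            rho, _, excluded, _, _ = sparcc_single_pass(frac, 0.1)
            assert len(excluded) <= 8
            off = np.abs(rho[np.triu_indices(20, 1)])
            assert np.percentile(off, 95) < 0.3


class TestSparccEstimate:
    def test_single_resample_equals_single_pass(self):
        b = sn.plant_correlation_network(8, 2, within_rho=0.5, seed=7)
        table, _ = sn.simulate_count_table(b, n_per_group=20, depth=2000, seed=8)
        est = sn.sparcc_estimate(table, n_resamples=1, seed=9)
        rng = np.random.default_rng(9)
        frac = np.column_stack(
            [dirichlet_fractions(table.counts[:, s], rng) for s in range(table.n_samples)]
        )
        rho, _, _, _, _ = sparcc_single_pass(frac)
        np.testing.assert_allclose(est.rho, np.clip(rho, -1, 1), atol=1e-12)

    def test_determinism(self):
        b = sn.plant_correlation_network(10, 2, within_rho=0.6, seed=10)
        table, _ = sn.simulate_count_table(b, n_per_group=15, depth=3000, seed=11)
        e1 = sn.sparcc_estimate(table, n_resamples=5, seed=12)
        e2 = sn.sparcc_estimate(table, n_resamples=5, seed=12)
        np.testing.assert_array_equal(e1.rho, e2.rho)

    def test_estimator_sklearn_contract(self):
        from sklearn.base import clone

        est = sn.SparCC(n_resamples=3, random_state=0)
        cloned = clone(est)
        assert cloned.get_params()["n_resamples"] == 3
        b = sn.plant_correlation_network(6, 2, within_rho=0.5, seed=13)
        table, _ = sn.simulate_count_table(b, n_per_group=10, depth=2000, seed=14)
        fitted = cloned.fit(table.counts.T)
        assert fitted.correlation_.shape == (6, 6)
        assert fitted.n_features_in_ == 6

    def test_consistency_error_shrinks_with_n(self):
        # median absolute error against planted truth decreases with n
        b = sn.plant_correlation_network(16, 2, hub_count=0, within_rho=0.6, seed=11)
        iu = np.triu_indices(16, 1)
        med = []
        for n in (25, 100, 400):
            table, _ = sn.simulate_count_table(b, n_per_group=n, depth=30_000, seed=12)
            est = sn.sparcc_estimate(table, n_resamples=5, seed=13)
            med.append(np.median(np.abs(est.rho - b.correlation)[iu]))
        assert med[0] > med[1] > med[2]

    @given(seed=st.integers(0, 50))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_estimate_is_valid_correlation_matrix(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 200, size=(5, 8))  # samples x taxa
        counts[:, 0] += 1  # no all-zero sample
        est = sn.SparCC(n_resamples=2, random_state=seed).fit(counts)
        r = est.correlation_
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)
        assert np.all(np.abs(r) <= 1.0)
        assert np.all(est.basis_variance_ > 0)

    def test_rejects_small_or_negative_input(self):
        with pytest.raises(ValueError):
            sn.SparCC().fit(np.ones((5, 3)))  # < 4 taxa
        with pytest.raises(ValueError):
            sn.SparCC().fit(-np.ones((5, 6)))
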