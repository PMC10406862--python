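"""Likelihood pieces and the per-spot maximum-likelihood fit."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist
from scipy.stats import poisson

from sonar.data import SpatialDataset
from sonar.model import (
    FitConfig,
    expected_rate,
    fit_all,
    fit_spot,
    local_weighted_loglik,
    nb_logpmf,
    poisson_logpmf,
    spot_loglik,
)


def quadrature_nb_logpmf(y, mu, alpha):
    """Independent oracle: numerically integrate the Poisson-Gamma mixture.

    P(y) = integral of Poisson(y; mu*v) * Gamma(v; alpha, rate=alpha) dv.
    """
    val, _ = quad(
        lambda v: poisson.pmf(y, mu * v) * gamma_dist.pdf(v, alpha, scale=1 / alpha),
        0, 50, limit=200,
    )
    return np.log(val)


class TestExpectedRate:
    def test_unit_weight_on_one_type_returns_its_signature(self):
        S = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        np.testing.assert_allclose(expected_rate([0, 0, 1], S), S[1])
        np.testing.assert_allclose(expected_rate([0, 1, 0], S), S[0])

    def test_zero_beta_gives_zero_rate(self):
        S = np.ones((2, 4))
        np.testing.assert_array_equal(expected_rate([0, 0, 0], S), np.zeros(4))

    def test_hand_computed_linear_form(self):
        S = np.array([[1.0, 0.0], [0.0, 3.0]])
        np.testing.assert_allclose(expected_rate([0.5, 1, 2], S), [1.5, 6.5])

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            expected_rate([1.0, 2.0], np.ones((2, 3)))


class TestNBLogPMF:
    def test_zero_mean_zero_count_is_certain(self):
        assert nb_logpmf(0, 0.0, 2.0) == 0.0

    def test_zero_mean_positive_count_is_sentinel_not_inf(self):
        val = nb_logpmf(3, 0.0, 2.0)
        assert np.isfinite(val) and val < -1e9

    def test_pmf_normalizes(self):
        y = np.arange(5001)
        total = np.exp(nb_logpmf(y, 3.0, 1.5)).sum()
        assert abs(total - 1.0) < 1e-10

    @pytest.mark.parametrize("mu", [0.5, 2.0, 10.0])
    @pytest.mark.parametrize("alpha", [0.3, 1.0, 5.0])
    def test_pmf_normalizes_on_grid(self, mu, alpha):
        y = np.arange(int(mu + 60 * np.sqrt(mu + mu**2 / alpha)) + 50)
        assert abs(np.exp(nb_logpmf(y, mu, alpha)).sum() - 1.0) < 1e-9

    def test_poisson_limit_at_huge_alpha(self):
        assert abs(nb_logpmf(4, 3.0, 1e8) - poisson.logpmf(4, 3.0)) < 1e-6

    @pytest.mark.parametrize(
        "y,mu,alpha", [(2, 1.7, 0.8), (0, 0.5, 3.0), (7, 4.2, 1.3)]
    )
    def test_matches_quadrature_oracle(self, y, mu, alpha):
        assert abs(nb_logpmf(y, mu, alpha) - quadrature_nb_logpmf(y, mu, alpha)) < 1e-6

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nb_logpmf(1, 1.0, 0.0)
        with pytest.raises(ValueError):
            nb_logpmf(1, 1.0, -2.0)
        with pytest.raises(ValueError):
            nb_logpmf(-1, 1.0, 1.0)


class TestSpotLoglik:
    def test_single_gene_reduces_to_nb_logpmf(self):
        S = np.array([[0.5], [1.5]])
        beta, alpha, depth = np.array([0.1, 1.0, 0.5]), 2.0, 100
        mu = depth * expected_rate(beta, S)[0]
        assert spot_loglik(beta, alpha, np.array([7]), depth, S) == pytest.approx(
            float(nb_logpmf(7, mu, alpha))
        )

    def test_sum_of_per_gene_terms(self):
        S = np.array([[1.0, 0.5, 2.0]])
        beta, alpha, depth = np.array([0.0, 1.2]), 1.7, 50
        row = np.array([3, 0, 12])
        mu = depth * expected_rate(beta, S)
        expected = sum(float(nb_logpmf(y, m, alpha)) for y, m in zip(row, mu))
        assert spot_loglik(beta, alpha, row, depth, S) == pytest.approx(expected)

    def test_zero_counts_loglik_decreases_as_beta_grows(self):
        S = np.ones((1, 5))
        row = np.zeros(5)
        lls = [
            spot_loglik(np.array([0.0, b]), 2.0, row, 10, S)
            for b in [0.01, 0.1, 1.0]
        ]
        assert lls[0] > lls[1] > lls[2]


class TestLocalWeightedLoglik:
    def _dataset(self):
        counts = np.array([[5, 1], [2, 3], [0, 4]])
        coords = np.array([[0.0, 0], [1, 0], [2, 0]])
        return SpatialDataset(counts=counts, coords=coords)

    def test_self_only_weights_equal_spot_loglik(self):
        ds = self._dataset()
        S = np.array([[1.0, 0.5]])
        beta, alpha = np.array([0.0, 0.8]), 2.0
        lhs = local_weighted_loglik(beta, alpha, 1, ds, S, {1: 1.0})
        rhs = spot_loglik(beta, alpha, ds.counts[1], ds.depth[1], S)
        assert lhs == pytest.approx(rhs)
        # zero-weight neighbours contribute nothing
        lhs2 = local_weighted_loglik(beta, alpha, 1, ds, S, {0: 0.0, 1: 1.0, 2: 0.0})
        assert lhs2 == pytest.approx(rhs)

    def test_three_spot_weighted_sum_oracle(self):
        ds = self._dataset()
        S = np.array([[1.0, 0.5]])
        beta, alpha = np.array([0.1, 0.8]), 2.0
        weights = {0: 0.5625, 1: 1.0, 2: 0.5625}
        expected = sum(
            w * spot_loglik(beta, alpha, ds.counts[n], ds.depth[n], S)
            for n, w in weights.items()
        )
        got = local_weighted_loglik(beta, alpha, 1, ds, S, weights)
        assert got == pytest.approx(expected)

    def test_focal_spot_must_be_in_weight_map(self):
        ds = self._dataset()
        with pytest.raises(ValueError):
            local_weighted_loglik(np.array([0, 1.0]), 2.0, 1, ds,
                                  np.array([[1.0, 0.5]]), {0: 1.0})


def _pure_type_dataset(S, which, depth, n_spots, rng):
    """Spots drawn Poisson from a single type's signature (rate-normalised)."""
    rates = S[which] / S[which].sum()
    counts = rng.poisson(depth * rates, size=(n_spots, S.shape[1]))
    coords = np.column_stack([np.arange(n_spots), np.zeros(n_spots)])
    return SpatialDataset(counts=counts, coords=coords)


class TestFitSpot:
    def test_recovers_generating_type(self, rng):
        rng2 = np.random.default_rng(5)
        S = np.vstack([rng2.uniform(0.1, 2.0, 200), rng2.uniform(0.1, 2.0, 200)])
        S[0, :30] *= 8  # distinct markers
        S[1, 30:60] *= 8
        ds = _pure_type_dataset(S, 1, depth=5000, n_spots=1, rng=rng)
        fit = fit_spot(0, ds, S, {0: 1.0}, FitConfig())
        props = fit.beta[1:] / fit.beta[1:].sum()
        assert np.argmax(props) == 1
        assert props[1] > 0.9

    def test_all_zero_counts_drive_beta_to_zero(self):
        ds = SpatialDataset(counts=np.zeros((1, 10)), coords=np.zeros((1, 2)))
        S = np.abs(np.random.default_rng(0).normal(1, 0.3, (3, 10)))
        fit = fit_spot(0, ds, S, {0: 1.0})
        assert fit.beta.max() < 1e-6

    def test_never_below_initialization_likelihood(self, rng):
        S = np.abs(rng.normal(1, 0.5, (3, 40))) + 0.05
        counts = rng.poisson(3.0, size=(1, 40))
        ds = SpatialDataset(counts=counts, coords=np.zeros((1, 2)))
        fit = fit_spot(0, ds, S, {0: 1.0})
        # initialization: NNLS beta, alpha = 10
        from sonar.model import _init_beta

        beta0 = _init_beta(ds.counts[0], ds.depth[0], S)
        init_ll = local_weighted_loglik(beta0, 10.0, 0, ds, S, {0: 1.0})
        assert fit.loglik >= init_ll - 1e-8

    def test_5050_mixture_recovered(self, rng):
        rng2 = np.random.default_rng(11)
        S = np.abs(rng2.normal(1, 0.5, (2, 150))) + 0.05
        S[0, :25] *= 6
        S[1, 25:50] *= 6
        mix = 0.5 * S[0] / S[0].sum() + 0.5 * S[1] / S[1].sum()
        props = []
        for _ in range(20):
            counts = rng.poisson(1e4 * mix / mix.sum(), size=(1, 150))
            ds = SpatialDataset(counts=counts, coords=np.zeros((1, 2)))
            fit = fit_spot(0, ds, S / S.sum(axis=1, keepdims=True), {0: 1.0})
            props.append(fit.beta[1:] / fit.beta[1:].sum())
        mean_prop = np.mean(props, axis=0)
        np.testing.assert_allclose(mean_prop, [0.5, 0.5], atol=0.05)


class _SingletonScheme:
    def __init__(self, n):
        self.n = n

    def weight_map(self, i):
        return {i: 1.0}


class _ZeroNeighborScheme:
    """Every spot sees its lattice neighbours, all at weight zero."""

    def __init__(self, n):
        self.n = n

    def weight_map(self, i):
        m = {i: 1.0}
        if i > 0:
            m[i - 1] = 0.0
        if i < self.n - 1:
            m[i + 1] = 0.0
        return m


class TestFitAll:
    def _two_pure_spots(self):
        rng = np.random.default_rng(3)
        S = np.abs(rng.normal(1, 0.4, (2, 120))) + 0.05
        S[0, :20] *= 7
        S[1, 20:40] *= 7
        S = S / S.sum(axis=1, keepdims=True)
        counts = np.vstack(
            [rng.poisson(8000 * S[0]), rng.poisson(8000 * S[1])]
        )
        ds = SpatialDataset(counts=counts, coords=np.array([[0.0, 0], [5.0, 0]]))
        return ds, S

    def test_pure_spots_give_identity_proportions(self):
        ds, S = self._two_pure_spots()
        res = fit_all(ds, S, _SingletonScheme(2))
        np.testing.assert_allclose(res.proportions, np.eye(2), atol=0.05)

    def test_zero_neighbor_weights_equal_independent_fits(self):
        ds, S = self._two_pure_spots()
        res_single = fit_all(ds, S, _SingletonScheme(2))
        res_zero = fit_all(ds, S, _ZeroNeighborScheme(2))
        np.testing.assert_array_equal(res_single.beta_matrix, res_zero.beta_matrix)
        np.testing.assert_array_equal(res_single.alpha_vector, res_zero.alpha_vector)

    def test_spot_order_does_not_matter(self):
        ds, S = self._two_pure_spots()
        perm = SpatialDataset(
            counts=ds.counts[::-1].copy(), coords=ds.coords[::-1].copy(),
            spot_ids=ds.spot_ids[::-1],
        )
        res = fit_all(ds, S, _SingletonScheme(2))
        res_perm = fit_all(perm, S, _SingletonScheme(2))
        np.testing.assert_allclose(
            res.beta_matrix, res_perm.beta_matrix[::-1], rtol=1e-12
        )

    def test_all_zero_spot_flagged_degenerate_with_uniform_row(self):
        ds, S = self._two_pure_spots()
        counts = ds.counts.copy()
        counts[1] = 0
        ds2 = SpatialDataset(counts=counts, coords=ds.coords)
        res = fit_all(ds2, S, _SingletonScheme(2))
        assert res.degenerate[1] and not res.degenerate[0]
        np.testing.assert_allclose(res.proportions[1], [0.5, 0.5])
        np.testing.assert_allclose(res.proportions.sum(axis=1), 1.0, atol=1e-8)


class TestPoissonMode:
    def test_poisson_logpmf_matches_scipy(self):
        y = np.arange(30)
        np.testing.assert_allclose(
            poisson_logpmf(y, 4.2), poisson.logpmf(y, 4.2), rtol=1e-12
        )

    def test_no_overdispersion_fit_has_infinite_alpha(self, rng):
        S = np.abs(rng.normal(1, 0.4, (2, 50))) + 0.05
        counts = rng.poisson(2.0, size=(1, 50))
        ds = SpatialDataset(counts=counts, coords=np.zeros((1, 2)))
        fit = fit_spot(0, ds, S, {0: 1.0}, FitConfig(overdispersion=False))
        assert np.isinf(fit.alpha)
        assert np.all(fit.beta >= 0)
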