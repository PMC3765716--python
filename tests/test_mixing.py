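"""Prior estimation: NPMLE of the mixing distribution and posterior algebra."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import poisson

from ebdiff import (
    CountFrequencyTable,
    MixingDistribution,
    eb_estimate,
    fit_npmle,
    fit_prior,
    g_to_q,
    mixture_pmf,
    posterior_lambda,
    q_to_g,
)
from ebdiff.mixing import conditional_log_likelihood

from conftest import random_mixing


class TestCountFrequencyTable:
    def test_from_counts_collapses_duplicates(self):
        t = CountFrequencyTable.from_counts([0, 0, 1, 5, 5, 5])
        assert t.counts.tolist() == [0, 1, 5]
        assert t.frequencies.tolist() == [2, 1, 3]
        assert t.n0 == 2

    def test_zero_counts_excluded_from_conditional_data(self):
        t = CountFrequencyTable.from_counts([0, 0, 3])
        x, n = t.positive()
        assert x.tolist() == [3] and n.tolist() == [1]

    def test_rejects_negative_and_fractional(self):
        with pytest.raises(ValueError):
            CountFrequencyTable.from_counts([-1, 2])
        with pytest.raises(ValueError):
            CountFrequencyTable.from_counts([1.5])


class TestNPMLE:
    def test_single_candidate_support_is_point_mass(self):
        t = CountFrequencyTable([5], [1000])
        q = fit_npmle(t, grid=[5.0])
        assert q.support.tolist() == [5.0]
        assert q.weights.tolist() == [1.0]

    def test_matches_bruteforce_two_point_maximum(self):
        # two distinct counts -> the NPMLE needs at most two support points;
        # enumerate every grid pair and optimise the mixing weight directly
        t = CountFrequencyTable([1, 10], [60, 40])
        grid = np.array([0.5] + list(range(1, 21)), dtype=float)
        q_hat = fit_npmle(t, grid=grid)
        ll_hat = conditional_log_likelihood(q_hat, t)

        def pair_ll(i, j, w):
            mix = MixingDistribution(
                np.array([grid[i], grid[j]]), np.array([w, 1.0 - w])
            )
            return conditional_log_likelihood(mix, t)

        best = -np.inf
        for i in range(grid.size):
            mix = MixingDistribution(grid[i : i + 1], [1.0])
            best = max(best, conditional_log_likelihood(mix, t))
            for j in range(i + 1, grid.size):
                res = minimize_scalar(
                    lambda w: -pair_ll(i, j, w),
                    bounds=(1e-9, 1 - 1e-9),
                    method="bounded",
                    options={"xatol": 1e-12},
                )
                best = max(best, -res.fun)
        assert ll_hat == pytest.approx(best, abs=1e-6)

    def test_dominates_single_point_truncated_mle(self, rng):
        counts = rng.poisson(rng.choice([3.0, 40.0], 500), 500)
        t = CountFrequencyTable.from_counts(counts)
        q_hat = fit_npmle(t)
        ll_hat = conditional_log_likelihood(q_hat, t)
        # best single-point competitor on a fine lambda sweep
        for lam in np.geomspace(0.1, 100, 300):
            single = MixingDistribution([lam], [1.0])
            assert ll_hat >= conditional_log_likelihood(single, t) - 1e-9

    def test_optimality_over_random_grid_mixtures(self, rng):
        counts = rng.poisson(rng.choice([2.0, 30.0], 400), 400)
        t = CountFrequencyTable.from_counts(counts)
        grid = np.geomspace(0.1, 80, 60)
        q_hat = fit_npmle(t, grid=grid)
        ll_hat = conditional_log_likelihood(q_hat, t)
        for _ in range(25):
            w = rng.dirichlet(np.ones(grid.size))
            rival = MixingDistribution(grid, w)
            assert ll_hat >= conditional_log_likelihood(rival, t) - 1e-7

    def test_all_zero_counts_raises(self):
        with pytest.raises(ValueError, match="no expressed genes"):
            fit_prior([0, 0, 0])

    def test_empty_grid_raises(self):
        t = CountFrequencyTable([3], [10])
        with pytest.raises(ValueError):
            fit_npmle(t, grid=[])

    def test_recovers_two_point_mixture_pmf(self):
        # The zero-count class is extrapolated through the (1 - e^-lambda)
        # untilt and is the fragile part of the recovery; see docs/methods.md.
        rng = np.random.default_rng(0)
        true = MixingDistribution([2.0, 50.0], [0.7, 0.3])
        lam = rng.choice(true.support, 10_000, p=true.weights)
        counts = rng.poisson(lam)
        g_hat = fit_prior(counts)
        xs = np.arange(0, 400)
        tv = 0.5 * np.abs(mixture_pmf(g_hat, xs) - mixture_pmf(true, xs)).sum()
        assert tv <= 0.02


class TestQGMapping:
    def test_point_mass_invariant(self):
        q = MixingDistribution([5.0], [1.0])
        g = q_to_g(q)
        assert g.support.tolist() == [5.0] and g.weights.tolist() == [1.0]

    def test_low_lambda_gains_mass_under_g(self):
        q = MixingDistribution([0.1, 10.0], [0.5, 0.5])
        g = q_to_g(q)
        expected = np.array([0.5 / -np.expm1(-0.1), 0.5 / -np.expm1(-10.0)])
        expected /= expected.sum()
        np.testing.assert_allclose(g.weights, expected, rtol=1e-12)
        assert g.weights[0] > q.weights[0]

    def test_round_trip_identity(self, rng):
        for _ in range(100):
            q = random_mixing(rng)
            back = g_to_q(q_to_g(q))
            np.testing.assert_allclose(back.weights, q.weights, atol=1e-12)
            np.testing.assert_array_equal(back.support, q.support)


class TestMixturePmf:
    def test_point_mass_equals_poisson(self):
        g = MixingDistribution([3.7], [1.0])
        xs = np.arange(0, 60)
        np.testing.assert_allclose(mixture_pmf(g, xs), poisson.pmf(xs, 3.7), rtol=1e-12)

    def test_two_term_sum_at_zero(self, two_point_prior):
        expected = 0.5 * np.exp(-1.0) + 0.5 * np.exp(-10.0)
        assert mixture_pmf(two_point_prior, 0) == pytest.approx(expected, rel=1e-12)

    def test_normalisation_of_fitted_prior(self, rng):
        counts = rng.poisson(rng.choice([2.0, 100.0], 2000, p=[0.6, 0.4]))
        g = fit_prior(counts)
        assert g.support.max() < 300
        assert mixture_pmf(g, np.arange(0, 501)).sum() >= 1 - 1e-10

    def test_negative_x_rejected(self, two_point_prior):
        with pytest.raises(ValueError):
            mixture_pmf(two_point_prior, -1)


class TestEmpiricalBayes:
    def test_point_mass_prior_fixed_point(self):
        g = MixingDistribution([7.3], [1.0])
        for x in range(0, 201):
            assert eb_estimate(g, x) == pytest.approx(7.3, abs=1e-10)

    def test_zero_count_gets_finite_positive_estimate(self, two_point_prior):
        lam = eb_estimate(two_point_prior, 0)
        assert np.isfinite(lam) and lam > 0

    def test_matches_posterior_mean_weighting(self, two_point_prior):
        # E[lambda | x=20] via explicit posterior weights
        w = two_point_prior.weights * poisson.pmf(20, two_point_prior.support)
        w /= w.sum()
        expected = float(w @ two_point_prior.support)
        assert eb_estimate(two_point_prior, 20) == pytest.approx(expected, abs=1e-10)

    def test_equals_posterior_mean_on_random_pairs(self, rng):
        for _ in range(100):
            g = random_mixing(rng)
            x = int(rng.integers(0, 150))
            post = posterior_lambda(g, x)
            assert abs(eb_estimate(g, x) - post.mean()) < 1e-10


class TestPosteriorLambda:
    def test_point_mass_prior_yields_point_mass(self):
        g = MixingDistribution([4.0], [1.0])
        for x in [0, 3, 50]:
            post = posterior_lambda(g, x)
            assert post.weights.tolist() == [1.0]

    def test_zero_count_two_term_normalisation(self, two_point_prior):
        post = posterior_lambda(two_point_prior, 0)
        expected = np.array([0.5 * np.exp(-1.0), 0.5 * np.exp(-10.0)])
        expected /= expected.sum()
        np.testing.assert_allclose(post.weights, expected, rtol=1e-10)
        assert post.weights[0] > 0.999

    def test_weights_sum_to_one(self, rng):
        for _ in range(20):
            g = random_mixing(rng)
            post = posterior_lambda(g, int(rng.integers(0, 300)))
            assert abs(post.weights.sum() - 1.0) < 1e-12
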