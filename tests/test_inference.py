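import numpy as np
import pytest
from scipy import stats

from molarisk.inference import (
    McmcConfig,
    PosteriorDraws,
    PosteriorSummary,
    PriorSpec,
    inv_logit,
    log_posterior_binomial_logit,
    logit,
    quadrature_posterior_1d,
    sample_posterior_1d,
    split_rhat,
    summarize_draws,
)


def make_draws(chains: np.ndarray) -> PosteriorDraws:
    chains = np.asarray(chains, dtype=float)
    return PosteriorDraws(
        name="a",
        draws=chains,
        acceptance_rate=np.full(chains.shape[0], 0.4),
        proposal_sd=np.ones(chains.shape[0]),
    )


class TestLogPosterior:
    def test_matches_scipy_densities_up_to_constant(self):
        """Independent oracle: binom.logpmf + norm.logpdf, same alpha-dependence."""
        rng = np.random.default_rng(9)
        prior = PriorSpec(-8.0, 3.0)
        y, n = 7, 200
        alphas = rng.normal(-3, 4, size=20)
        mine = log_posterior_binomial_logit(alphas, y, n, prior)
        oracle = stats.binom.logpmf(y, n, inv_logit(alphas)) + stats.norm.logpdf(
            alphas, prior.mean, prior.sd
        )
        diff = mine - oracle
        assert np.allclose(diff, diff[0])  # constant offset only

    def test_empty_likelihood_is_prior_density(self):
        prior = PriorSpec(-8.0, 3.0)
        a = np.array([-10.0, -8.0, 0.0])
        expected = -0.5 * ((a - prior.mean) / prior.sd) ** 2
        assert np.allclose(log_posterior_binomial_logit(a, 0, 0, prior), expected)

    def test_boundary_counts_finite(self):
        prior = PriorSpec(-8.0, 3.0)
        for y, n in [(0, 50), (50, 50)]:
            vals = log_posterior_binomial_logit(np.array([-30.0, 0.0, 10.0]), y, n, prior)
            assert np.all(np.isfinite(vals))

    def test_flat_prior_mode_is_mle(self):
        """With a nearly flat prior the posterior mode approaches logit(y/n)."""
        from scipy.optimize import minimize_scalar

        prior = PriorSpec(0.0, 1e6)
        res = minimize_scalar(
            lambda a: -log_posterior_binomial_logit(a, 5, 10, prior), bounds=(-5, 5), method="bounded"
        )
        assert abs(res.x - 0.0) < 1e-4  # logit(0.5) = 0

    def test_y_above_n_rejected(self):
        with pytest.raises(ValueError):
            log_posterior_binomial_logit(0.0, 5, 3, PriorSpec(-8, 3))


class TestSampler:
    def test_prior_recovery_when_no_data(self):
        prior = PriorSpec(-8.0, 3.0)
        d = sample_posterior_1d(0, 0, prior, McmcConfig(seed=1))
        pooled = d.pooled()
        ess_floor = 500  # conservative for 8000 correlated draws
        mc_se = pooled.std() / np.sqrt(ess_floor)
        assert abs(pooled.mean() - prior.mean) < 3 * mc_se

    def test_fixed_seed_is_bitwise_reproducible(self):
        cfg = McmcConfig(seed=77)
        d1 = sample_posterior_1d(3, 5000, PriorSpec(-8, 3), cfg)
        d2 = sample_posterior_1d(3, 5000, PriorSpec(-8, 3), cfg)
        assert np.array_equal(d1.draws, d2.draws)

    def test_different_seeds_differ(self):
        d1 = sample_posterior_1d(3, 5000, PriorSpec(-8, 3), McmcConfig(seed=1))
        d2 = sample_posterior_1d(3, 5000, PriorSpec(-8, 3), McmcConfig(seed=2))
        assert not np.array_equal(d1.draws, d2.draws)

    def test_acceptance_rate_in_efficient_band(self):
        d = sample_posterior_1d(3, 5000, PriorSpec(-8, 3), McmcConfig(seed=4))
        assert np.all(d.acceptance_rate > 0.2) and np.all(d.acceptance_rate < 0.6)

    def test_median_matches_quadrature(self):
        prior = PriorSpec(-8.0, 3.0)
        d = sample_posterior_1d(3, 5000, prior, McmcConfig(seed=6))
        mcmc_median = summarize_draws(d, transform=inv_logit).median
        quad_median = quadrature_posterior_1d(3, 5000, prior).p.median
        assert mcmc_median == pytest.approx(quad_median, rel=0.05)


class TestQuadrature:
    def test_prior_only_median_is_prior_mean(self):
        q = quadrature_posterior_1d(0, 0, PriorSpec(-8, 3))
        assert q.alpha.median == pytest.approx(-8.0, abs=1e-3)

    def test_symmetric_likelihood_dominated_case(self):
        q = quadrature_posterior_1d(500, 1000, PriorSpec(0, 1000))
        assert q.p.median == pytest.approx(0.5, abs=1e-3)

    def test_matches_scipy_quad_inversion(self):
        """Independent oracle: adaptive quadrature + root finding on the CDF."""
        from scipy import integrate, optimize

        y, n, prior = 2, 800, PriorSpec(-8.0, 3.0)

        def dens(a):
            return np.exp(log_posterior_binomial_logit(a, y, n, prior))

        z, _ = integrate.quad(dens, -40, 10, limit=200)
        med = optimize.brentq(
            lambda a: integrate.quad(dens, -40, a, limit=200)[0] / z - 0.5, -30, 5
        )
        q = quadrature_posterior_1d(y, n, prior)
        assert q.alpha.median == pytest.approx(med, abs=1e-3)

    def test_probability_centiles_commute_with_transform(self):
        """Monotone transform: centiles of expit(alpha) = expit(centiles of alpha)."""
        q = quadrature_posterior_1d(3, 5000, PriorSpec(-8, 3))
        assert q.p.median == pytest.approx(float(inv_logit(q.alpha.median)), rel=1e-12)
        assert q.p.q2_5 == pytest.approx(float(inv_logit(q.alpha.q2_5)), rel=1e-12)
        assert q.p.q97_5 == pytest.approx(float(inv_logit(q.alpha.q97_5)), rel=1e-12)


class TestSummaries:
    def test_constant_draws(self):
        s = summarize_draws(make_draws(np.full((2, 10), 3.0)))
        assert (s.q2_5, s.median, s.q97_5) == (3.0, 3.0, 3.0)

    def test_empirical_median_definition(self):
        s = summarize_draws(make_draws(np.arange(1, 101, dtype=float).reshape(2, 50)))
        assert s.median == 50.5

    def test_median_commutes_with_monotone_transform_odd_count(self):
        rng = np.random.default_rng(0)
        draws = make_draws(rng.normal(-8, 3, size=(3, 33)))
        s_alpha = summarize_draws(draws)
        s_p = summarize_draws(draws, transform=inv_logit)
        assert s_p.median == pytest.approx(float(inv_logit(s_alpha.median)), rel=1e-12)

    def test_prior_pushforward_median(self):
        rng = np.random.default_rng(3)
        draws = make_draws(rng.normal(-8, 3, size=(4, 5001)))
        s = summarize_draws(draws, transform=inv_logit)
        assert s.median == pytest.approx(float(inv_logit(-8)), rel=0.1)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            PosteriorSummary(1.0, 0.5, 2.0)


class TestSplitRhat:
    def test_identical_constant_chains_convention(self):
        assert split_rhat(make_draws(np.full((3, 100), 2.0))) == 1.0

    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(11)
        r = split_rhat(make_draws(rng.normal(size=(4, 2000))))
        assert r < 1.01

    def test_offset_chains_flagged(self):
        rng = np.random.default_rng(12)
        chains = rng.normal(size=(2, 500))
        chains[1] += 10.0
        assert split_rhat(make_draws(chains)) > 1.5

    def test_matches_arviz(self):
        az = pytest.importorskip("arviz")
        d = sample_posterior_1d(3, 5000, PriorSpec(-8, 3), McmcConfig(seed=21))
        theirs = float(az.rhat(az.from_dict({"a": d.draws}))["a"].values)
        assert split_rhat(d) == pytest.approx(theirs, abs=2e-3)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            split_rhat(make_draws(np.zeros((1, 100))))


class TestShrinkage:
    @pytest.mark.parametrize("y,n", [(1, 1000), (3, 5000), (28, 12424)])
    def test_posterior_median_between_prior_and_mle(self, y, n):
        prior = PriorSpec(-8.0, 3.0)
        med = quadrature_posterior_1d(y, n, prior).p.median
        lo, hi = sorted([float(inv_logit(prior.mean)), y / n])
        assert lo < med < hi
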