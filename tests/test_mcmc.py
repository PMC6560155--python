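import math

import numpy as np
import pytest
from scipy import stats

from aarratio import (
    BCMState,
    MCMCConfig,
    StratifiedCountTable,
    bcm_intervals,
    car_conditional,
    log_likelihood,
    log_prior,
    posterior_predictive_counts,
    rook_lattice,
    run_mcmc,
    run_uh_model,
    sample_tau_u,
    sample_tau_v,
)
from aarratio.mcmc import PosteriorSample


def _flat_state(I, **kw):
    base = dict(alpha0=0.0, v=np.zeros(I), u=np.zeros(I),
                tau_v=1.0, tau_u=1.0, sigma_alpha=1.0)
    base.update(kw)
    return BCMState(**base)


def _table(counts, pop):
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    pop = np.atleast_2d(np.asarray(pop, dtype=float))
    I, J = counts.shape
    return StratifiedCountTable(
        [f"r{i}" for i in range(I)], [f"a{j}" for j in range(J)], counts, pop
    )


class TestLogLikelihood:
    def test_hand_values(self):
        # Pois(D=2; 1): 2*ln1 - 1 - ln2 = -1.693147;  Pois(D=0; 1): -1
        t = _table([[2]], [[1e4]])
        e = np.array([[1.0]])
        assert log_likelihood(_flat_state(1), t, e) == pytest.approx(-1.0 - math.log(2))
        t0 = _table([[0]], [[1e4]])
        assert log_likelihood(_flat_state(1), t0, e) == pytest.approx(-1.0)

    def test_scipy_oracle(self, rng):
        I, J = 6, 3
        counts = rng.integers(0, 30, size=(I, J)).astype(float)
        pop = rng.uniform(1e3, 1e4, size=(I, J))
        e = rng.uniform(1.0, 20.0, size=(I, J))
        state = _flat_state(I, alpha0=0.2, v=rng.normal(0, 0.1, I), u=rng.normal(0, 0.1, I))
        lam = e * state.theta()[:, None]
        expected = stats.poisson.logpmf(counts, lam).sum()
        t = _table(counts, pop)
        assert log_likelihood(state, t, e) == pytest.approx(expected)

    def test_zero_mean_positive_count_rejected(self):
        t = _table([[3]], [[1e3]])
        with pytest.raises(ValueError):
            log_likelihood(_flat_state(1), t, np.array([[0.0]]))


class TestLogPrior:
    def test_term_by_term_oracle(self):
        adj, _ = rook_lattice(2, 2)
        cfg = MCMCConfig(n_iter=10, n_burn=1)
        u = np.array([0.1, -0.1, 0.2, -0.2])
        v = np.array([0.3, -0.3, 0.1, -0.1])
        state = BCMState(0.5, v, u, tau_v=2.0, tau_u=3.0, sigma_alpha=1.5)
        quad = sum((u[i] - u[j]) ** 2 for i, j in adj.edges())
        expected = (
            stats.norm.logpdf(0.5, scale=1.5)
            + 2.0 * math.log(2.0) - 0.5 * 2.0 * np.sum(v**2)
            + 2.0 * math.log(3.0) - 0.5 * 3.0 * quad
            + stats.gamma.logpdf(3.0, a=2.0, scale=2.0)
            + stats.gamma.logpdf(2.0, a=2.0, scale=2.0)
            - math.log(100.0)
        )
        assert log_prior(state, adj, cfg) == pytest.approx(expected)

    def test_sigma_alpha_out_of_bounds(self):
        cfg = MCMCConfig(n_iter=10, n_burn=1)
        state = _flat_state(4, sigma_alpha=150.0)
        adj, _ = rook_lattice(2, 2)
        assert log_prior(state, adj, cfg) == -np.inf

    def test_no_adjacency_drops_car_terms(self):
        cfg = MCMCConfig(n_iter=10, n_burn=1)
        adj, _ = rook_lattice(2, 2)
        s1 = _flat_state(4, u=np.array([0.5, -0.5, 0.2, -0.2]))
        s2 = _flat_state(4, u=np.zeros(4))
        # without adjacency, u does not enter the prior
        assert log_prior(s1, None, cfg) == pytest.approx(log_prior(s2, None, cfg))
        assert log_prior(s1, adj, cfg) < log_prior(s2, adj, cfg)


class TestCARConditional:
    def test_moments_example(self):
        adj, _ = rook_lattice(1, 3)  # path A-B-C
        u = np.array([1.0, 2.0, 5.0])
        mean, var = car_conditional(u, adj, tau_u=4.0, region=1)
        assert mean == pytest.approx(3.0)  # (1 + 5) / 2
        assert var == pytest.approx(1.0 / 8.0)  # 1 / (4 * 2 neighbours)

    def test_grid_proportional_to_joint_prior(self):
        # the normal with car_conditional moments must match the joint CAR
        # prior as a function of u_i up to an additive constant
        adj, _ = rook_lattice(2, 3)
        cfg = MCMCConfig(n_iter=10, n_burn=1)
        rng = np.random.default_rng(8)
        u = rng.normal(size=6)
        tau_u = 2.5
        i = 2
        mean, var = car_conditional(u, adj, tau_u, i)
        grid = np.linspace(-2, 2, 9)
        joint, cond = [], []
        for g in grid:
            uu = u.copy()
            uu[i] = g
            state = _flat_state(6, u=uu, tau_u=tau_u)
            joint.append(log_prior(state, adj, cfg))
            cond.append(stats.norm.logpdf(g, loc=mean, scale=math.sqrt(var)))
        diff = np.array(joint) - np.array(cond)
        assert np.ptp(diff) == pytest.approx(0.0, abs=1e-9)


class TestPrecisionSampling:
    def test_tau_v_matches_gamma_moments(self):
        cfg = MCMCConfig(n_iter=10, n_burn=1, gamma_shape=2.0, gamma_rate=0.5)
        v = np.array([0.4, -0.2, 0.1, -0.3, 0.5])
        rng = np.random.default_rng(3)
        draws = np.array([sample_tau_v(v, cfg, rng) for _ in range(20_000)])
        shape = 2.0 + 2.5
        rate = 0.5 + 0.5 * np.sum(v**2)
        assert draws.mean() == pytest.approx(shape / rate, rel=0.03)
        assert draws.var() == pytest.approx(shape / rate**2, rel=0.06)

    def test_tau_u_matches_gamma_moments(self):
        adj, _ = rook_lattice(2, 2)
        cfg = MCMCConfig(n_iter=10, n_burn=1)
        u = np.array([0.2, -0.2, 0.3, -0.3])
        quad = sum((u[i] - u[j]) ** 2 for i, j in adj.edges())
        rng = np.random.default_rng(4)
        draws = np.array([sample_tau_u(u, adj, cfg, rng) for _ in range(20_000)])
        shape, rate = 2.0 + 2.0, 0.5 + 0.5 * quad
        assert draws.mean() == pytest.approx(shape / rate, rel=0.03)


@pytest.fixture(scope="module")
def small_fit():
    """A short but real chain on a 4x5 lattice, one age stratum."""
    rng = np.random.default_rng(21)
    adj, _ = rook_lattice(4, 5)
    pop = rng.uniform(2e4, 8e4, size=(20, 1))
    theta_true = np.exp(rng.normal(0.0, 0.25, size=20))
    base = 1.5e-3
    counts = rng.poisson(base * pop[:, 0] * theta_true).astype(float)[:, None]
    table = _table(counts, pop)
    cfg = MCMCConfig(n_iter=4000, n_burn=2000, thin=2, seed=5)
    sample = run_mcmc(table, adj, cfg)
    return table, adj, sample, theta_true


class TestSampler:
    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        adj, _ = rook_lattice(2, 3)
        pop = np.full((6, 1), 5e4)
        counts = rng.poisson(60, size=(6, 1)).astype(float)
        table = _table(counts, pop)
        cfg = MCMCConfig(n_iter=600, n_burn=300, thin=3, seed=17)
        s1 = run_mcmc(table, adj, cfg)
        s2 = run_mcmc(table, adj, cfg)
        assert np.array_equal(s1.theta, s2.theta)
        assert np.array_equal(s1.tau_u, s2.tau_u)
        s3 = run_mcmc(table, adj, MCMCConfig(n_iter=600, n_burn=300, thin=3, seed=18))
        assert not np.array_equal(s1.theta, s3.theta)

    def test_u_draws_centered(self, small_fit):
        _, _, sample, _ = small_fit
        assert np.max(np.abs(sample.u.mean(axis=1))) < 1e-10

    def test_acceptance_rates_reasonable(self, small_fit):
        _, _, sample, _ = small_fit
        for name, rate in sample.acceptance_rates.items():
            assert 0.05 < rate < 0.8, (name, rate)

    def test_theta_tracks_crude_risk(self, small_fit):
        table, _, sample, theta_true = small_fit
        post = sample.theta.mean(axis=0)
        rho = stats.spearmanr(post, theta_true).statistic
        assert rho > 0.5

    def test_uh_matches_bcm_with_pinned_car(self):
        # with tau_u pinned huge, u collapses to ~0 and the convolution model
        # reduces to the exchangeable-only model
        rng = np.random.default_rng(30)
        adj, _ = rook_lattice(3, 4)
        pop = np.full((12, 1), 5e4)
        counts = rng.poisson(80, size=(12, 1)).astype(float)
        table = _table(counts, pop)
        cfg_b = MCMCConfig(n_iter=4000, n_burn=2000, thin=2, seed=9, fix_tau_u=1e8)
        cfg_u = MCMCConfig(n_iter=4000, n_burn=2000, thin=2, seed=9)
        b = run_mcmc(table, adj, cfg_b)
        u = run_uh_model(table, cfg_u)
        assert np.max(np.abs(b.u.mean(axis=0))) < 1e-2
        assert b.theta.mean(axis=0) == pytest.approx(u.theta.mean(axis=0), rel=0.05)


def _null_sample(expected, G=8000):
    I, J = expected.shape
    return PosteriorSample(
        alpha0=np.zeros(G),
        v=np.zeros((G, I)),
        u=np.zeros((G, I)),
        tau_v=np.ones(G),
        tau_u=np.ones(G),
        sigma_alpha=np.ones(G),
        theta=np.ones((G, I)),
        expected=np.asarray(expected, dtype=float),
        region_ids=[f"r{i}" for i in range(I)],
        age_labels=[f"a{j}" for j in range(J)],
        acceptance_rates={},
    )


class TestPosteriorPrediction:
    def test_predictive_mean_matches_expected(self):
        e = np.array([[40.0, 60.0], [80.0, 20.0]])
        sample = _null_sample(e)
        t = _table([[40, 60], [80, 20]], [[1e4, 1e4], [1e4, 1e4]])
        pred = posterior_predictive_counts(sample, t, seed=1)
        assert pred.shape == (8000, 2, 2)
        assert pred.mean(axis=0) == pytest.approx(e, rel=0.03)

    def test_predictive_variance_is_poisson(self):
        e = np.array([[50.0]])
        pred = posterior_predictive_counts(_null_sample(e, G=20_000),
                                           _table([[50]], [[1e4]]), seed=2)
        assert pred.var() == pytest.approx(50.0, rel=0.05)

    def test_determinism(self):
        e = np.array([[30.0], [70.0]])
        s = _null_sample(e, G=100)
        t = _table([[30], [70]], [[1e4], [1e4]])
        assert np.array_equal(
            posterior_predictive_counts(s, t, seed=7),
            posterior_predictive_counts(s, t, seed=7),
        )


class TestBCMIntervals:
    def test_null_model_ratio_near_one(self):
        # theta = 1 everywhere, equal expected counts: all RR intervals
        # straddle 1 and the point estimates sit near 1
        e = np.full((6, 2), 45.0)
        t = _table(e, np.full((6, 2), 3e4))
        sample = _null_sample(e)
        rates_df, ratios_df = bcm_intervals(sample, t, [0.5, 0.5], seed=3)
        assert ratios_df["estimate"].to_numpy() == pytest.approx(1.0, abs=0.02)
        assert np.all(ratios_df["lower"] <= 1.0)
        assert np.all(ratios_df["upper"] >= 1.0)

    def test_single_region_rate_poisson_quantile_oracle(self):
        # one stratum, theta = 1: the AAR draws are Poisson(e)/n * 1e5, so
        # the percentile endpoints must match exact Poisson quantiles
        e = np.array([[50.0], [50.0]])
        n = 1e5
        t = _table(e, [[n], [n]])
        sample = _null_sample(e, G=40_000)
        rates_df, _ = bcm_intervals(sample, t, [1.0], seed=4, level=0.95)
        row = rates_df[rates_df["region_id"] == "r0"].iloc[0]
        scale = 1e5 / n
        assert row["lower"] == pytest.approx(stats.poisson.ppf(0.025, 50) * scale, abs=2 * scale)
        assert row["upper"] == pytest.approx(stats.poisson.ppf(0.975, 50) * scale, abs=2 * scale)
        assert row["estimate"] == pytest.approx(50.0 * scale, rel=0.02)

    def test_overall_row_present(self):
        e = np.full((4, 1), 30.0)
        t = _table(e, np.full((4, 1), 2e4))
        rates_df, ratios_df = bcm_intervals(_null_sample(e, G=2000), t, [1.0], seed=5)
        assert "__overall__" in set(rates_df["region_id"])
        assert "__overall__" not in set(ratios_df["region_id"])

    def test_calibration_smoke(self, small_fit):
        # fitted intervals should cover the generating relative risks for the
        # bulk of regions (posterior-predictive intervals are conservative)
        table, _, sample, theta_true = small_fit
        _, ratios_df = bcm_intervals(sample, table, [1.0], seed=6)
        # generating truth on the ratio scale
        pop = table.population[:, 0]
        rr_true = theta_true / (np.sum(pop * theta_true) / pop.sum())
        inside = (ratios_df["lower"].to_numpy() <= rr_true) & (
            rr_true <= ratios_df["upper"].to_numpy()
        )
        assert inside.mean() >= 0.8
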