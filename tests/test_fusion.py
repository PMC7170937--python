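"""Likelihood, priors, sampler and diagnostics."""

import dataclasses

import numpy as np
import pytest

from pyrocycle.carbon_model import simulate
from pyrocycle.fusion import (
    ObservationSet,
    ObsStream,
    Posterior,
    PriorEntry,
    PriorSpec,
    convergence_diag,
    default_priors,
    log_likelihood,
    log_prior,
    mh_sample,
    modelled_streams,
    posterior_predict,
    random_walk_metropolis,
)
from pyrocycle.fusion import INIT_POOL_NAMES
from pyrocycle.types import PARAM_NAMES, PoolState

from conftest import constant_forcing

LOG2PI = np.log(2 * np.pi)


@pytest.fixture(scope="module")
def traj(savanna_params):
    init = PoolState(labile=20, foliar=100, fine_root=120, wood=800,
                     litter=150, som=5000, water=100)
    return simulate(savanna_params, init, constant_forcing(24, ba=0.02))


def perfect_obs(traj, lcma, sd=1.0):
    m = modelled_streams(traj, lcma)
    return ObservationSet(
        lai=ObsStream(values=m["lai"], sd=sd, times=np.arange(24)),
        gpp_anom=ObsStream(values=m["gpp_anom"], sd=sd, times=np.arange(24)),
        biomass=ObsStream(values=m["biomass"], sd=sd),
        som=ObsStream(values=m["som"], sd=sd),
        fire_annual=ObsStream(values=m["fire_annual"], sd=sd,
                              times=np.arange(2)),
    )


class TestLogLikelihood:
    def test_value_at_mode_with_unit_sd(self, traj, savanna_params):
        obs = perfect_obs(traj, savanna_params.lcma)
        n = obs.n_points
        assert n == 24 + 24 + 1 + 1 + 2
        got = log_likelihood(traj, obs, lcma=savanna_params.lcma)
        assert got == pytest.approx(-(n / 2) * LOG2PI, rel=1e-12)

    def test_stream_dropout_leaves_other_terms_unchanged(self, traj,
                                                         savanna_params):
        obs = perfect_obs(traj, savanna_params.lcma)
        full = log_likelihood(traj, obs, lcma=savanna_params.lcma)
        no_lai = dataclasses.replace(obs, lai=None)
        lai_only = ObservationSet(lai=obs.lai)
        assert log_likelihood(traj, no_lai, lcma=savanna_params.lcma) \
            + log_likelihood(traj, lai_only, lcma=savanna_params.lcma) \
            == pytest.approx(full, rel=1e-12)

    def test_inflating_sd_helps_a_poor_fit(self, traj, savanna_params):
        m = modelled_streams(traj, savanna_params.lcma)
        bad = ObservationSet(
            biomass=ObsStream(values=m["biomass"] + 10.0, sd=1.0))
        worse = ObservationSet(
            biomass=ObsStream(values=m["biomass"] + 10.0, sd=2.0))
        assert log_likelihood(traj, worse, lcma=savanna_params.lcma) \
            > log_likelihood(traj, bad, lcma=savanna_params.lcma)

    def test_zero_sd_rejected(self, traj, savanna_params):
        obs = ObservationSet(biomass=ObsStream(values=[800.0], sd=[0.0]))
        with pytest.raises(ValueError):
            log_likelihood(traj, obs, lcma=savanna_params.lcma)


class TestLogPrior:
    def test_outside_bounds_is_minus_inf(self):
        prior = PriorSpec([PriorEntry("lue", "loguniform", 0.1, 1.0)])
        assert log_prior(np.array([2.0]), prior) == -np.inf

    def test_loguniform_constant_in_log_space(self):
        e = PriorEntry("r", "loguniform", 0.01, 1.0)
        # density 1/(x log(b/a)): log f(x) + log x is the same everywhere
        assert e.logpdf(0.02) + np.log(0.02) == pytest.approx(
            e.logpdf(0.5) + np.log(0.5), rel=1e-12)

    def test_truncnorm_density_ratio_closed_form(self):
        e = PriorEntry("t", "truncnorm", 0.0, 10.0, mu=5.0, sigma=2.0)
        got = e.logpdf(6.0) - e.logpdf(4.0)
        # normalization cancels; ratio is exp(-(1^2 - 1^2)/(2*4)) = 1
        assert got == pytest.approx(0.0, abs=1e-12)
        got2 = e.logpdf(7.0) - e.logpdf(5.0)
        assert got2 == pytest.approx(-(2.0**2) / (2 * 4.0), abs=1e-12)

    def test_allocation_sum_constraint(self):
        prior = default_priors()
        x = prior.midpoint()
        idx = {n: i for i, n in enumerate(prior.names)}
        x[idx["alloc_foliar"]] = 0.5
        x[idx["alloc_labile"]] = 0.4
        x[idx["alloc_root"]] = 0.3
        assert log_prior(x, prior) == -np.inf

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            log_prior(np.ones(3), default_priors())

    def test_transform_round_trip(self):
        prior = default_priors()
        x = prior.midpoint()
        z = prior.to_transformed(x)
        np.testing.assert_allclose(prior.from_transformed(z), x, rtol=1e-9)


def batch_mcse(x: np.ndarray, n_batch: int = 50) -> float:
    """Monte-Carlo standard error of the mean by batch means."""
    m = x.size // n_batch
    means = x[: m * n_batch].reshape(n_batch, m).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batch))


class TestSampler:
    def test_identical_seed_identical_chain(self, fixture_bundle):
        fx = fixture_bundle
        kw = dict(n_iter=2000, n_burn=1000, seed=42)
        p1 = mh_sample(fx.obs, fx.forcing, **kw)
        p2 = mh_sample(fx.obs, fx.forcing, **kw)
        np.testing.assert_array_equal(p1.samples, p2.samples)
        assert p1.acceptance_rate == p2.acceptance_rate

    def test_conjugate_normal_normal_recovery(self):
        """One Gaussian observation with known variance and a Gaussian
        location prior: the MH posterior must match the analytic conjugate
        posterior within Monte-Carlo error."""
        y, sigma2 = 1.5, 1.0
        mu0, tau02 = 0.0, 4.0
        post_var = 1.0 / (1.0 / tau02 + 1.0 / sigma2)
        post_mean = post_var * (mu0 / tau02 + y / sigma2)

        def log_target(z):
            th = z[0]
            return (-0.5 * (th - mu0) ** 2 / tau02
                    - 0.5 * (y - th) ** 2 / sigma2)

        samples, _, rate = random_walk_metropolis(
            log_target, np.array([0.0]), n_iter=50_000, n_burn=10_000,
            scales=1.0, seed=17, thin=1)
        th = samples[:, 0]
        se_mean = batch_mcse(th)
        assert th.mean() == pytest.approx(post_mean, abs=3 * se_mean)
        ess = (th.std() / se_mean) ** 2
        se_sd = th.std() / np.sqrt(2 * ess)
        assert th.std(ddof=1) == pytest.approx(np.sqrt(post_var), abs=3 * se_sd)
        assert 0.05 < rate < 0.8

    def test_prior_only_chain_samples_the_prior(self, fixture_bundle):
        """With no observations the chain must reproduce prior quantiles."""
        fx = fixture_bundle
        post = mh_sample(ObservationSet(), fx.forcing, n_iter=40_000, seed=5)
        prior = default_priors()
        e = prior["lue"]
        logs = np.log(post.column("lue"))
        lo, hi = np.log(e.lo), np.log(e.hi)
        expected = lo + (hi - lo) * np.array([0.25, 0.5, 0.75])
        got = np.quantile(logs, [0.25, 0.5, 0.75])
        np.testing.assert_allclose(got, expected, atol=0.2 * (hi - lo) / 4)

    def test_invalid_iteration_counts_rejected(self, fixture_bundle):
        fx = fixture_bundle
        with pytest.raises(ValueError):
            mh_sample(fx.obs, fx.forcing, n_iter=0, seed=1)
        with pytest.raises(ValueError):
            mh_sample(fx.obs, fx.forcing, n_iter=100, n_burn=100, seed=1)

    def test_posterior_round_trip_csv(self, fixture_bundle, tmp_path):
        fx = fixture_bundle
        post = mh_sample(fx.obs, fx.forcing, n_iter=1000, n_burn=500, seed=3)
        path = tmp_path / "post.csv"
        post.to_csv(path)
        back = Posterior.from_csv(path)
        np.testing.assert_allclose(back.samples, post.samples, rtol=1e-12)
        assert back.names == post.names
        assert back.seed == post.seed


class TestPosteriorPredict:
    def _degenerate_posterior(self, savanna_params, n=4):
        row = np.concatenate([savanna_params.as_array(),
                              [20, 100, 120, 800, 150, 5000]])
        names = list(PARAM_NAMES) + list(INIT_POOL_NAMES)
        return Posterior(samples=np.tile(row, (n, 1)), names=names,
                         log_post=np.zeros(n), acceptance_rate=0.3, seed=0)

    def test_degenerate_ensemble_collapses_quartiles(self, savanna_params):
        post = self._degenerate_posterior(savanna_params)
        out = posterior_predict(post, constant_forcing(12), n_draws=4, seed=0)
        q = out["gpp"]
        np.testing.assert_array_equal(q[0], q[1])
        np.testing.assert_array_equal(q[1], q[2])

    def test_quantiles_are_ordered(self, fixture_bundle):
        fx = fixture_bundle
        post = mh_sample(fx.obs, fx.forcing, n_iter=2000, n_burn=1000, seed=9)
        out = posterior_predict(post, fx.forcing, n_draws=20, seed=1)
        for q in out.values():
            assert np.all(q[0] <= q[1] + 1e-12)
            assert np.all(q[1] <= q[2] + 1e-12)

    def test_three_draw_median_is_middle_run(self, savanna_params):
        post = self._degenerate_posterior(savanna_params, n=3)
        # make the three draws differ only in lue -> ranked GPP
        i = post.names.index("lue")
        post.samples[0, i] = 0.2
        post.samples[1, i] = 0.3
        post.samples[2, i] = 0.4
        f = constant_forcing(12)
        out = posterior_predict(post, f, n_draws=3, seed=0)
        from pyrocycle.carbon_model import simulate as sim
        params, init = post.draw(1)
        mid = sim(params, init.replace(water=100.0), f)
        np.testing.assert_allclose(out["gpp"][1], mid.gpp, rtol=1e-12)

    def test_empty_posterior_rejected(self, savanna_params):
        post = self._degenerate_posterior(savanna_params)
        with pytest.raises(ValueError):
            posterior_predict(post, constant_forcing(12), n_draws=10, seed=0)


class TestConvergenceDiag:
    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = [rng.normal(0, 1, (2000, 2)) for _ in range(3)]
        rh = convergence_diag(chains)
        assert all(abs(v - 1.0) < 0.05 for v in rh.values())

    def test_disjoint_constant_chains_diverge(self):
        c1 = np.zeros((100, 1))
        c2 = np.ones((100, 1))
        rh = convergence_diag([c1, c2])
        assert rh["p0"] > 10

    def test_toy_chains_match_hand_formula(self):
        c1 = np.array([1.0, 2.0, 3.0, 4.0])[:, None]
        c2 = np.array([2.0, 3.0, 4.0, 5.0])[:, None]
        # split halves: [1,2],[3,4],[2,3],[4,5]; W = 0.5,
        # half-means (1.5, 3.5, 2.5, 4.5) -> B/n = 5/3
        w = 0.5
        var_hat = (2 - 1) / 2 * w + 5 / 3
        expected = np.sqrt(var_hat / w)
        rh = convergence_diag([c1, c2])
        assert rh["p0"] == pytest.approx(expected, rel=1e-12)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            convergence_diag([np.zeros((10, 1))])
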