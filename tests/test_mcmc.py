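"""Adaptive Metropolis-within-Gibbs machinery and both samplers."""

import numpy as np
import pytest
from scipy import stats

import ballstick as bs
from ballstick.mcmc import adaptation_factor
from ballstick.nuisance import NuisanceEstimates
from ballstick.sphere import rotation_to_z


@pytest.fixture(scope="module")
def exact_nuisance():
    return NuisanceEstimates(400.0, 1 / 1500, 0.9, np.array([0.0, 0.0, 1.0]),
                             rotation_to_z([0.0, 0.0, 1.0]))


class TestLogLikelihood:
    def test_zero_residual_closed_form(self):
        sig = np.ones(10)
        assert bs.log_likelihood(sig, sig, 2.0) == \
            pytest.approx(-5.0 * np.log(2 * np.pi * 4.0))

    def test_doubling_sigma(self):
        sig = np.ones(8)
        assert bs.log_likelihood(sig, sig, 1.0) - bs.log_likelihood(sig, sig, 2.0) == \
            pytest.approx(8.0 * np.log(2.0))

    def test_matches_pointwise_normal_sum(self, rng):
        sig = rng.standard_normal(30)
        pred = rng.standard_normal(30)
        oracle = stats.norm.logpdf(sig, loc=pred, scale=3.0).sum()
        assert bs.log_likelihood(sig, pred, 3.0) == pytest.approx(oracle, abs=1e-10)

    def test_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            bs.log_likelihood(np.ones(3), np.ones(3), 0.0)


class TestPropose:
    def test_degenerate_epsilon(self, rng):
        assert bs.propose(1.5, 0.0, rng) == 1.5

    def test_moments(self):
        rng = np.random.default_rng(0)
        draws = np.array([bs.propose(2.0, 0.7, rng) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(2.0, abs=0.01)
        assert draws.std() == pytest.approx(0.7, rel=0.02)


class TestGibbsPrecision:
    def test_posterior_mean_matches_closed_form(self):
        rng = np.random.default_rng(1)
        resid = np.full(50, 2.0)          # SSR = 200
        shape, rate = 3.0, 1.0
        draws = np.array([1.0 / bs.gibbs_update_precision(resid, shape, rate, rng) ** 2
                          for _ in range(100_000)])
        expected = (shape + 25.0) / (rate + 100.0)
        assert draws.mean() == pytest.approx(expected, rel=0.02)

    def test_positive_and_prior_limit(self):
        rng = np.random.default_rng(2)
        sig = np.array([bs.gibbs_update_precision(np.empty(0), 200.0, 1.0, rng)
                        for _ in range(2000)])
        assert np.all(sig > 0)
        # with no data the precision is a pure prior draw, mean ~ shape/rate
        assert (1.0 / sig ** 2).mean() == pytest.approx(200.0, rel=0.05)


class TestAdaptation:
    def test_first_batch_factor(self):
        # min(e^0.01, e^1) = e^0.01
        assert adaptation_factor(1) == pytest.approx(np.exp(0.01), rel=1e-12)

    def test_diminishing(self):
        assert adaptation_factor(10 ** 8) == pytest.approx(1.0, abs=1e-3)
        assert adaptation_factor(100) <= adaptation_factor(1)

    def test_direction_of_adaptation(self):
        eps = np.array([1.0, 1.0, 1.0])
        out = bs.adapt_proposals(eps, np.array([0.0, 0.44, 1.0]), batch_index=1)
        d = np.exp(0.01)
        np.testing.assert_allclose(out, [1.0 / d, 1.0, d], rtol=1e-12)


class TestConjugateSmokeTest:
    def test_normal_mean_posterior_quantiles(self):
        # 1-parameter conjugate problem: y ~ N(mu, s^2) with flat prior on mu;
        # the same adaptive-MH loop must reproduce the analytic posterior
        rng = np.random.default_rng(5)
        s, n = 2.0, 40
        y = rng.normal(1.0, s, size=n)
        post_mean, post_sd = y.mean(), s / np.sqrt(n)
        mu, eps, acc = 0.0, 1.0, 0
        keep = []
        n_iter = 100_000
        for t in range(n_iter):
            cand = bs.propose(mu, eps, rng)
            logr = (np.sum((y - mu) ** 2) - np.sum((y - cand) ** 2)) / (2 * s * s)
            if np.log(rng.random()) < logr:
                mu, acc = cand, acc + 1
            if (t + 1) % 50 == 0:
                eps = float(bs.adapt_proposals(np.array([eps]),
                                               np.array([acc / 50.0]),
                                               (t + 1) // 50)[0])
                acc = 0
            keep.append(mu)
        kept = np.array(keep[n_iter // 2::10])
        ks = stats.kstest(kept, lambda x: stats.norm.cdf(x, post_mean, post_sd))
        assert ks.statistic < 0.02


class TestSimplifiedSampler:
    def test_noiseless_recovery(self, paper_scenario, clean_signal, exact_nuisance):
        _, protocol = paper_scenario
        cfg = bs.MCMCConfig(n_iter=20_000, thin=5, seed=2)
        chain = bs.run_simplified_mcmc(clean_signal, protocol, exact_nuisance, cfg)
        summ = bs.summarize_posterior(chain, cfg, exact_nuisance)
        # truth in the rotated frame (identity): azimuths 60 and 120 deg
        got = sorted([summ.median["phi1p"], summ.median["phi2p"]])
        assert np.degrees(got[0]) == pytest.approx(60.0, abs=3.0)
        assert np.degrees(got[1]) == pytest.approx(120.0, abs=3.0)
        fr = sorted(summ.fractions)
        assert fr[0] == pytest.approx(0.4, abs=0.05)
        assert fr[1] == pytest.approx(0.5, abs=0.05)

    def test_seeded_determinism(self, paper_scenario, clean_signal, exact_nuisance):
        _, protocol = paper_scenario
        noisy = bs.add_noise(clean_signal, 20.0, 3)
        cfg = bs.MCMCConfig(n_iter=5000, seed=42)
        a = bs.run_simplified_mcmc(noisy, protocol, exact_nuisance, cfg)
        b = bs.run_simplified_mcmc(noisy, protocol, exact_nuisance, cfg)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_label_exchange_invariance(self, paper_scenario):
        # swapping (phi'_1, phi'_2) and (f1, F-f1) leaves the mean model fixed
        _, protocol = paper_scenario
        a = bs.predict_signal_simplified(0.3, 1.0, 2.0, 400, 1 / 1500, 0.9, protocol)
        b = bs.predict_signal_simplified(0.6, 2.0, 1.0, 400, 1 / 1500, 0.9, protocol)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_isotropic_voxel_rejected(self, paper_scenario, clean_signal):
        _, protocol = paper_scenario
        bad = NuisanceEstimates(400.0, 1 / 1500, 0.0, np.array([0, 0, 1.0]),
                                np.eye(3))
        with pytest.raises(ValueError, match="isotropic"):
            bs.run_simplified_mcmc(clean_signal, protocol, bad)


class TestFullSampler:
    def test_noiseless_one_fiber_recovery(self):
        proto = bs.make_protocol(64, n_b0=4, with_hypothetical=False)
        truth = bs.VoxelGroundTruth(fibers=[bs.FiberComponent.from_angles(0.7, 0.0, 60.0)],
                                    sigma=0.0)
        clean = bs.predict_signal(truth, proto)
        cfg = bs.MCMCConfig(n_iter=20_000, thin=5, seed=4)
        chain = bs.run_full_mcmc(clean, proto, cfg,
                                 init={"S0": 400.0, "d": 1 / 1500, "f1": 0.5,
                                       "f2": 0.0, "theta1": 0.0, "phi1": 1.0,
                                       "theta2": 0.0, "phi2": 2.0, "sigma": 10.0})
        summ = bs.summarize_posterior(chain, cfg)
        assert summ.fractions.sum() == pytest.approx(0.7, abs=0.05)
        main = summ.directions[int(np.argmax(summ.fractions))]
        assert bs.angular_separation(main, bs.direction_from_angles(0.0, 60.0)) < 5.0

    def test_sigma_posterior_matches_conjugate_prediction(self, paper_scenario,
                                                          clean_signal):
        # the Gamma(200, 1) precision prior is sharp: the posterior sits at the
        # prior-data compromise, not at the data noise level
        _, protocol = paper_scenario
        noisy = bs.add_noise(clean_signal, 20.0, 6)
        cfg = bs.MCMCConfig(n_iter=20_000, thin=5, seed=5)
        chain = bs.run_full_mcmc(noisy, protocol, cfg,
                                 init={"S0": 400.0, "d": 1 / 1500, "f1": 0.4,
                                       "f2": 0.5, "theta1": 0.0, "phi1": np.pi / 3,
                                       "theta2": 0.0, "phi2": 2 * np.pi / 3,
                                       "sigma": 20.0})
        summ = bs.summarize_posterior(chain, cfg)
        n = len(protocol)
        ssr = n * 20.0 ** 2  # residuals ~ noise at the posterior mode
        predicted = np.sqrt((1.0 + ssr / 2) / (200.0 + n / 2))
        assert summ.median["sigma"] == pytest.approx(predicted, rel=0.15)


class TestSummaries:
    def test_constant_chain(self, exact_nuisance):
        samples = np.tile([0.4, 1.0, 2.0, 20.0], (2000, 1))
        state = bs.ChainState(samples, ["f1", "phi1p", "phi2p", "sigma"],
                              np.ones(3), np.ones(3), "simplified")
        cfg = bs.MCMCConfig(n_iter=2000, thin=1)
        summ = bs.summarize_posterior(state, cfg, exact_nuisance)
        assert summ.median["f1"] == 0.4
        assert summ.sd["f1"] == pytest.approx(0.0, abs=1e-12)
        assert summ.median["f2"] == pytest.approx(0.5)

    def test_thinning_consistency(self, paper_scenario, clean_signal, exact_nuisance):
        _, protocol = paper_scenario
        noisy = bs.add_noise(clean_signal, 20.0, 9)
        cfg1 = bs.MCMCConfig(n_iter=20_000, thin=1, seed=7)
        cfg10 = bs.MCMCConfig(n_iter=20_000, thin=10, seed=7)
        chain = bs.run_simplified_mcmc(noisy, protocol, exact_nuisance, cfg1)
        s1 = bs.summarize_posterior(chain, cfg1, exact_nuisance)
        s10 = bs.summarize_posterior(chain, cfg10, exact_nuisance)
        assert s1.median["f1"] == pytest.approx(s10.median["f1"], abs=0.02)

    def test_identity_back_rotation(self, exact_nuisance):
        samples = np.tile([0.4, np.deg2rad(60.0), np.deg2rad(120.0), 20.0],
                          (1000, 1))
        state = bs.ChainState(samples, ["f1", "phi1p", "phi2p", "sigma"],
                              np.ones(3), np.ones(3), "simplified")
        summ = bs.summarize_posterior(state, bs.MCMCConfig(n_iter=1000), exact_nuisance)
        assert summ.median["theta1_deg"] == pytest.approx(0.0, abs=1e-9)
        assert summ.median["phi1_deg"] == pytest.approx(60.0, abs=1e-9)

    def test_too_short_chain_errors(self, exact_nuisance):
        state = bs.ChainState(np.zeros((0, 4)), ["f1", "phi1p", "phi2p", "sigma"],
                              np.ones(3), np.ones(3), "simplified")
        with pytest.raises(ValueError):
            bs.summarize_posterior(state, bs.MCMCConfig(), exact_nuisance)


def test_iteration_cost_ratio():
    # parameter-count / likelihood-evaluation accounting: the simplified
    # sampler is at least ~5x cheaper per iteration than the full sampler
    simp = bs.iteration_cost("simplified", n_dw=64)
    full = bs.iteration_cost("full", n_dw=64, n_total=72)
    assert full / simp >= 5.0
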