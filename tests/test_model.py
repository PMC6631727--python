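"""Backbone model: prior, transition mixture, emitter, joint density."""

import numpy as np
import pytest
from scipy.stats import norm

from tsldmf._ad import softplus_inv
from tsldmf.model import (VAR_FLOOR, GenerativeParams, emitter_distribution,
                          initial_prior, joint_log_prob, params_from_ssm,
                          sample_trajectory, transition_distribution)
from tsldmf.simulate import generate_linear_gaussian_ssm

from oracles import joint_gaussian_loglik


@pytest.fixture(scope="module")
def params2d():
    return GenerativeParams(latent_dim=2, obs_dim=24, mixture_K=1, seed=0)


@pytest.fixture(scope="module")
def params_mix():
    return GenerativeParams(latent_dim=2, obs_dim=6, mixture_K=3, seed=1)


class TestInitialPrior:
    def test_standard_normal_log_density_at_origin(self, params2d):
        prior = initial_prior(params2d)
        np.testing.assert_allclose(prior.mean, 0.0, atol=1e-12)
        np.testing.assert_allclose(prior.var, 1.0, rtol=1e-9)
        assert prior.log_prob(np.zeros(2)) == pytest.approx(-np.log(2 * np.pi))

    def test_sample_mean_within_monte_carlo_error(self, params2d):
        prior = initial_prior(params2d)
        draws = prior.sample(np.random.default_rng(0), n=10_000)
        assert np.all(np.abs(draws.mean(axis=0) - prior.mean) < 4 / 100)

    def test_density_integrates_to_one_on_grid(self, params2d):
        prior = initial_prior(params2d)
        xs = np.linspace(-8, 8, 201)
        xx, yy = np.meshgrid(xs, xs)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        integral = np.exp(prior.log_prob(pts)).sum() * (xs[1] - xs[0]) ** 2
        assert integral == pytest.approx(1.0, abs=0.01)


class TestTransition:
    def test_constant_network_is_independent_of_input(self):
        p = GenerativeParams(latent_dim=2, mixture_K=1, hidden=(), seed=0)
        p.transition_net.layers[0].weight.data[:] = 0.0
        a = transition_distribution(np.array([0.0, 0.0]), p)
        b = transition_distribution(np.array([5.0, -3.0]), p)
        np.testing.assert_allclose(a.means, b.means)
        np.testing.assert_allclose(a.vars, b.vars)

    def test_mixture_log_density_matches_direct_summation(self, params_mix):
        rng = np.random.default_rng(2)
        mix = transition_distribution(rng.normal(size=2), params_mix)
        for z in rng.normal(size=(20, 2)):
            direct = np.log(sum(
                w * np.prod(norm.pdf(z, m, np.sqrt(v)))
                for w, m, v in zip(mix.weights, mix.means, mix.vars)))
            assert mix.log_prob(z) == pytest.approx(direct, rel=1e-9)

    def test_weights_sum_to_one_for_random_inputs(self, params_mix):
        rng = np.random.default_rng(3)
        for z in rng.normal(scale=3, size=(100, 2)):
            mix = transition_distribution(z, params_mix)
            assert mix.weights.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(mix.weights >= 0) and np.all(mix.vars > 0)

    def test_non_finite_input_rejected(self, params2d):
        with pytest.raises(ValueError):
            transition_distribution(np.array([np.inf, 0.0]), params2d)


class TestEmitter:
    def test_identity_readout_reproduces_latent(self):
        # d = 24 diagnostic configuration with an affine emitter set to the
        # identity on the mean block
        p = GenerativeParams(latent_dim=24, obs_dim=24, hidden=(), seed=0)
        layer = p.emitter_net.layers[0]
        layer.weight.data[:] = 0.0
        layer.weight.data[:, :24] = np.eye(24)
        layer.bias.data[:] = 0.0
        z = np.random.default_rng(4).normal(size=24)
        np.testing.assert_allclose(emitter_distribution(z, p).mean, z,
                                   atol=1e-12)

    def test_log_density_is_maximal_at_the_mean(self, params2d):
        rng = np.random.default_rng(5)
        z = rng.normal(size=2)
        dist = emitter_distribution(z, params2d)
        at_mode = dist.log_prob(dist.mean)
        for _ in range(20):
            assert at_mode >= dist.log_prob(dist.mean + rng.normal(size=24))

    def test_log_density_matches_per_coordinate_sum(self, params2d):
        rng = np.random.default_rng(6)
        dist = emitter_distribution(rng.normal(size=2), params2d)
        y = rng.normal(size=24)
        direct = norm.logpdf(y, dist.mean, np.sqrt(dist.var)).sum()
        assert dist.log_prob(y) == pytest.approx(direct, rel=1e-9)

    def test_latent_dimension_mismatch_rejected(self, params2d):
        with pytest.raises(ValueError):
            emitter_distribution(np.zeros(5), params2d)

    def test_binned_emitter_normalizes_and_scores(self):
        p = GenerativeParams(latent_dim=2, obs_dim=6, hidden=(8,),
                             emitter_family="multinomial", n_bins=16, seed=7)
        dist = emitter_distribution(np.zeros(2), p)
        np.testing.assert_allclose(dist.probs.sum(axis=1), 1.0, rtol=1e-9)
        y = np.full(6, 0.5)
        assert np.isfinite(dist.log_prob(y))
        assert np.all((dist.mean > 0) & (dist.mean < 1))


class TestJointLogProb:
    def test_base_case_is_prior_plus_emission(self, params2d):
        rng = np.random.default_rng(8)
        z, y = rng.normal(size=(1, 2)), rng.normal(size=(1, 24))
        expected = initial_prior(params2d).log_prob(z[0]) \
            + emitter_distribution(z[0], params2d).log_prob(y[0])
        assert joint_log_prob(y, z, params2d) == pytest.approx(expected)

    def test_telescoping_additivity(self, params2d):
        rng = np.random.default_rng(9)
        z, y = rng.normal(size=(4, 2)), rng.normal(size=(4, 24))
        step = transition_distribution(z[2], params2d).log_prob(z[3]) \
            + emitter_distribution(z[3], params2d).log_prob(y[3])
        assert joint_log_prob(y, z, params2d) == pytest.approx(
            joint_log_prob(y[:3], z[:3], params2d) + step)

    def test_matches_term_by_term_oracle(self, params2d):
        rng = np.random.default_rng(10)
        z, y = rng.normal(size=(6, 2)), rng.normal(size=(6, 24))
        total = initial_prior(params2d).log_prob(z[0])
        for t in range(6):
            if t > 0:
                total += transition_distribution(z[t - 1], params2d).log_prob(z[t])
            total += emitter_distribution(z[t], params2d).log_prob(y[t])
        assert joint_log_prob(y, z, params2d) == pytest.approx(total, rel=1e-12)

    def test_length_mismatch_rejected(self, params2d):
        with pytest.raises(ValueError):
            joint_log_prob(np.zeros((3, 24)), np.zeros((2, 2)), params2d)


class TestSampling:
    def test_same_seed_reproduces_trajectory(self, params2d):
        z1, y1 = sample_trajectory(params2d, T=10, seed=3)
        z2, y2 = sample_trajectory(params2d, T=10, seed=3)
        np.testing.assert_array_equal(z1, z2)
        np.testing.assert_array_equal(y1, y2)

    def test_zero_variance_limit_tracks_mean_recursion(self):
        p = GenerativeParams(latent_dim=2, obs_dim=4, hidden=(), seed=11)
        tiny = softplus_inv(1e-12)
        p.prior_rawvar.data[:] = tiny
        p.transition_net.layers[0].bias.data[1 + 2:] = tiny
        p.emitter_net.layers[0].bias.data[4:] = tiny
        zs, _ = sample_trajectory(p, T=5, seed=0)
        z = initial_prior(p).mean
        for t in range(1, 6):
            z, _ = transition_distribution(z, p).moments()
            # variances are floored at 1e-4, so each step can wander ~0.01
            np.testing.assert_allclose(zs[t], z, atol=0.1)

    def test_one_step_sample_covariance_matches_transition(self, params2d):
        z_prev = np.array([0.4, -0.2])
        mix = transition_distribution(z_prev, params2d)
        draws = mix.sample(np.random.default_rng(12), n=10_000)
        m, v = mix.moments()
        np.testing.assert_allclose(draws.mean(axis=0), m,
                                   atol=4 * np.sqrt(v.max() / 10_000) + 1e-3)
        np.testing.assert_allclose(draws.var(axis=0), v, rtol=0.1)


class TestLinearGaussianEquivalence:
    def test_joint_log_prob_matches_multivariate_normal_oracle(self):
        ssm = generate_linear_gaussian_ssm(2, 3, T=5, seed=13)
        params = params_from_ssm(ssm)
        # conditional p(y | z) x p(z) assembled from scipy pieces
        manual = norm.logpdf(ssm.z[0], ssm.init_mean,
                             np.sqrt(ssm.init_var)).sum()
        for t in range(len(ssm.y)):
            if t > 0:
                manual += norm.logpdf(ssm.z[t], ssm.coeffs * ssm.z[t - 1],
                                      np.sqrt(ssm.process_var)).sum()
            manual += norm.logpdf(ssm.y[t], ssm.emission @ ssm.z[t],
                                  np.sqrt(ssm.obs_var)).sum()
        assert joint_log_prob(ssm.y, ssm.z, params) == pytest.approx(
            manual, abs=1e-6)

    def test_marginal_likelihood_consistency(self):
        # the stacked joint-Gaussian marginal equals the Kalman-free oracle
        ssm = generate_linear_gaussian_ssm(1, 2, T=4, seed=14)
        from oracles import kalman_filter
        _, _, ll = kalman_filter(ssm, ssm.y)
        assert ll == pytest.approx(joint_gaussian_loglik(ssm, ssm.y), abs=1e-8)

    def test_emitted_parameters_finite_on_wide_box(self, params2d):
        rng = np.random.default_rng(15)
        for z in rng.uniform(-10, 10, size=(50, 2)):
            e = emitter_distribution(z, params2d)
            t = transition_distribution(z, params2d)
            assert np.all(np.isfinite(e.mean)) and np.all(np.isfinite(e.var))
            assert np.all(np.isfinite(t.means)) and np.all(t.vars > 0)


def test_checkpoint_roundtrip(tmp_path, params2d):
    params2d.save(tmp_path / "p.npz")
    loaded = GenerativeParams.load(tmp_path / "p.npz")
    z = np.array([0.3, -0.8])
    np.testing.assert_allclose(
        emitter_distribution(z, loaded).mean,
        emitter_distribution(z, params2d).mean)
    np.testing.assert_allclose(
        transition_distribution(z, loaded).means,
        transition_distribution(z, params2d).means)
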