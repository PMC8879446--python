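"""Class-conditional Gaussian fits, densities and Bayes posteriors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.stats import multivariate_normal

from mutualcl import (
    class_posterior,
    class_prior,
    fit_class_conditionals,
    fit_gaussian,
    gaussian_log_density,
)
from mutualcl.exceptions import (
    DegenerateCovarianceError,
    EmptySampleError,
    MissingClassError,
    ValidationError,
)
from mutualcl.gaussian_bayes import GaussianSummary, PosteriorTable


class TestFitGaussian:
    def test_two_point_hand_case(self):
        g = fit_gaussian(np.array([[0.0], [2.0]]), ridge=0.0)
        assert g.mean[0] == pytest.approx(1.0)
        assert g.covariance[0, 0] == pytest.approx(2.0)  # ((0-1)^2+(2-1)^2)/(2-1)

    def test_identical_points_zero_spread(self):
        pts = np.tile([0.3, 0.7], (10, 1))
        g = fit_gaussian(pts, ridge=1e-4)
        np.testing.assert_allclose(g.mean, [0.3, 0.7])
        np.testing.assert_allclose(g.covariance, 0.0, atol=1e-15)
        np.testing.assert_allclose(g.effective_covariance(), 1e-4 * np.eye(2), atol=1e-15)

    def test_parameter_recovery_3d(self):
        rng = np.random.default_rng(42)
        mean = np.array([1.0, -2.0, 0.5])
        cov = np.array([[1.0, 0.3, 0.0], [0.3, 2.0, -0.4], [0.0, -0.4, 0.7]])
        draws = rng.multivariate_normal(mean, cov, size=10_000)
        g = fit_gaussian(draws, ridge=0.0)
        np.testing.assert_allclose(g.mean, mean, atol=0.05)
        np.testing.assert_allclose(g.covariance, cov, atol=0.1)

    def test_mean_bias_shrinks_with_n(self):
        rng = np.random.default_rng(7)
        errs = []
        for n in (100, 10_000):
            draws = rng.normal(2.0, 1.0, size=(n, 1))
            errs.append(abs(fit_gaussian(draws, ridge=0).mean[0] - 2.0))
        assert errs[1] < errs[0]

    def test_errors(self):
        with pytest.raises(EmptySampleError):
            fit_gaussian(np.empty((0, 2)))
        with pytest.raises(ValidationError):
            fit_gaussian(np.array([[np.nan, 1.0]]))
        with pytest.raises(DegenerateCovarianceError):
            fit_gaussian(np.array([[1.0, 2.0]]), ridge=0.0)


class TestLogDensity:
    def test_standard_normal_at_mode(self):
        g = GaussianSummary(mean=np.zeros(1), covariance=np.eye(1), count=2, ridge=0.0)
        assert gaussian_log_density(np.zeros(1), g) == pytest.approx(
            -0.5 * np.log(2 * np.pi)
        )

    @pytest.mark.parametrize("d", [1, 3, 5])
    def test_value_at_mean_is_normalizer(self, d, rng):
        a = rng.normal(size=(d, d))
        cov = a @ a.T + 0.5 * np.eye(d)
        g = GaussianSummary(mean=rng.normal(size=d), covariance=cov, count=10, ridge=1e-3)
        eff = g.effective_covariance()
        expected = -0.5 * (d * np.log(2 * np.pi) + np.log(np.linalg.det(eff)))
        assert gaussian_log_density(g.mean, g) == pytest.approx(expected)

    def test_matches_scipy(self, rng):
        d = 4
        a = rng.normal(size=(d, d))
        g = GaussianSummary(
            mean=rng.normal(size=d), covariance=a @ a.T, count=20, ridge=1e-4
        )
        pts = rng.normal(size=(6, d))
        ref = multivariate_normal(mean=g.mean, cov=g.effective_covariance()).logpdf(pts)
        np.testing.assert_allclose(g.log_density(pts), ref, rtol=1e-10)

    def test_quadrature_normalization_1d(self):
        g = fit_gaussian(np.array([[0.4], [1.1], [0.2], [0.9]]), ridge=1e-4)
        sigma = np.sqrt(g.effective_covariance()[0, 0])
        mu = g.mean[0]
        val, _ = integrate.quad(
            lambda x: np.exp(gaussian_log_density(np.array([x]), g)),
            mu - 10 * sigma,
            mu + 10 * sigma,
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_monte_carlo_normalization_3d(self):
        """Importance-sampled integral of the density is 1 (n=1e6, tol 1e-2)."""
        rng = np.random.default_rng(5)
        a = rng.normal(size=(3, 3))
        g = GaussianSummary(
            mean=rng.normal(size=3), covariance=a @ a.T + np.eye(3), count=10, ridge=1e-4
        )
        q_cov = 4.0 * g.effective_covariance()
        draws = rng.multivariate_normal(g.mean, q_cov, size=1_000_000)
        log_q = multivariate_normal(mean=g.mean, cov=q_cov).logpdf(draws)
        est = np.exp(g.log_density(draws) - log_q).mean()
        assert est == pytest.approx(1.0, abs=1e-2)

    def test_density_gradient_matches_finite_difference(self, rng):
        d = 3
        a = rng.normal(size=(d, d))
        g = GaussianSummary(mean=rng.normal(size=d), covariance=a @ a.T, count=5, ridge=1e-3)
        pt = rng.normal(size=d)
        grad = g.density_gradient(pt)[0]
        eps = 1e-6
        for j in range(d):
            e = np.zeros(d)
            e[j] = eps
            fd = (g.log_density(pt + e) - g.log_density(pt - e))[0] / (2 * eps)
            assert grad[j] == pytest.approx(fd, rel=1e-5)

    def test_dimension_mismatch(self):
        g = fit_gaussian(np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValidationError):
            gaussian_log_density(np.zeros(3), g)


class TestClassPrior:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            (["a", "a", "b", "b"], [0.5, 0.5]),
            (["a", "a", "a"], [1.0]),
            (["a", "a", "a", "b"], [0.75, 0.25]),
        ],
    )
    def test_ratios(self, labels, expected):
        prior = class_prior(labels)
        np.testing.assert_allclose(prior.probs, expected)
        assert prior.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_registry_order_and_zero_counts(self):
        prior = class_prior(["b", "b", "c"], registry=["a", "b", "c"])
        assert prior.class_ids == ["a", "b", "c"]
        np.testing.assert_allclose(prior.probs, [0.0, 2 / 3, 1 / 3])
        assert np.isneginf(prior.log_probs()[0])

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            class_prior([])


class TestClassConditionals:
    def test_single_class_reduces_to_fit_gaussian(self):
        old = np.array([[1.0, 0.0], [0.0, 1.0]])
        new = np.array([[0.5, 0.5], [0.2, 0.8]])
        joint = np.concatenate([old, new], axis=1)
        conds = fit_class_conditionals(old, new, ["a", "a"], ridge=1e-4)
        direct = fit_gaussian(joint, ridge=1e-4)
        np.testing.assert_allclose(conds["a"].mean, direct.mean)
        np.testing.assert_allclose(conds["a"].covariance, direct.covariance)

    def test_cluster_mean_recovery(self, rng):
        centers = {"a": np.array([0.8, 0.2]), "b": np.array([0.1, 0.9])}
        old, new, labels = [], [], []
        for cls, c in centers.items():
            for _ in range(500):
                old.append(c + rng.normal(0, 0.01, 2))
                new.append(c[::-1] + rng.normal(0, 0.01, 2))
                labels.append(cls)
        conds = fit_class_conditionals(np.array(old), np.array(new), labels)
        for cls, c in centers.items():
            np.testing.assert_allclose(conds[cls].mean[:2], c, atol=0.05)
            np.testing.assert_allclose(conds[cls].mean[2:], c[::-1], atol=0.05)

    def test_concatenation_order_symmetry(self, rng):
        """Permuting the stream concatenation permutes nothing observable."""
        old = rng.dirichlet(np.ones(3), size=8)
        new = rng.dirichlet(np.ones(2), size=8)
        labels = ["a"] * 4 + ["b"] * 4
        fwd = fit_class_conditionals(old, new, labels, ridge=1e-3)
        rev = fit_class_conditionals(new, old, labels, ridge=1e-3)
        pts_fwd = np.concatenate([old, new], axis=1)
        pts_rev = np.concatenate([new, old], axis=1)
        for cls in ("a", "b"):
            np.testing.assert_allclose(
                fwd[cls].log_density(pts_fwd), rev[cls].log_density(pts_rev), rtol=1e-10
            )

    def test_missing_width_errors(self):
        with pytest.raises(ValidationError):
            fit_class_conditionals(np.empty((2, 0)), np.ones((2, 1)), ["a", "a"])


def _random_bayes_instance(rng, n=20, w=4, d=3):
    conds = {}
    names = [f"c{i}" for i in range(w)]
    for cls in names:
        a = rng.normal(size=(d, d))
        conds[cls] = GaussianSummary(
            mean=rng.normal(size=d), covariance=a @ a.T + np.eye(d), count=10, ridge=1e-6
        )
    prior = class_prior(list(rng.choice(names, size=50)), registry=names)
    pts = rng.normal(size=(n, d))
    return conds, prior, pts


class TestPosterior:
    def test_equal_likelihoods_return_prior(self):
        g = GaussianSummary(mean=np.zeros(2), covariance=np.eye(2), count=5, ridge=0.0)
        prior = class_prior(["a"] * 9 + ["b"], registry=["a", "b"])
        table = class_posterior({"a": g, "b": g}, prior, np.zeros((3, 2)))
        np.testing.assert_allclose(table.posterior, [[0.9, 0.1]] * 3, rtol=1e-12)

    def test_likelihood_ratio_two_to_one(self):
        # two 1-d unit Gaussians whose densities differ by a factor 2 at x
        g1 = GaussianSummary(mean=np.zeros(1), covariance=np.eye(1), count=5, ridge=0.0)
        x = np.sqrt(2 * np.log(2.0))  # N(x|0,1)/N(x|sqrt..,.) = 2 when mu2 at x
        g2 = GaussianSummary(mean=np.array([x]), covariance=np.eye(1), count=5, ridge=0.0)
        prior = class_prior(["a", "b"], registry=["a", "b"])
        table = class_posterior({"a": g2, "b": g1}, prior, np.array([[x]]))
        np.testing.assert_allclose(table.posterior[0], [2 / 3, 1 / 3], rtol=1e-10)

    def test_matches_direct_space_oracle(self, rng):
        conds, prior, pts = _random_bayes_instance(rng)
        table = class_posterior(conds, prior, pts)
        # direct-space Bayes: multiply densities and priors, normalize, no logs
        dens = np.stack(
            [np.exp(conds[c].log_density(pts)) for c in prior.class_ids], axis=1
        )
        direct = dens * prior.probs
        direct /= direct.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(table.posterior, direct, atol=1e-9, rtol=1e-9)

    def test_rows_sum_to_one_and_shift_invariance(self, rng):
        conds, prior, pts = _random_bayes_instance(rng, n=50)
        table = class_posterior(conds, prior, pts)
        np.testing.assert_allclose(table.posterior.sum(axis=1), 1.0, atol=1e-9)
        # adding a constant to a row of log-likelihoods leaves the posterior alone
        shifted = table.log_likelihood + 3.7
        joint = shifted + prior.log_probs()
        from scipy.special import logsumexp

        log_post = joint - logsumexp(joint, axis=1, keepdims=True)
        np.testing.assert_allclose(log_post, table.log_posterior, atol=1e-9)

    def test_missing_conditional_errors(self):
        g = GaussianSummary(mean=np.zeros(1), covariance=np.eye(1), count=5, ridge=0.0)
        prior = class_prior(["a", "b"], registry=["a", "b"])
        with pytest.raises(MissingClassError):
            class_posterior({"a": g}, prior, np.zeros((1, 1)))

    def test_zero_prior_class_gets_minus_inf(self):
        g = GaussianSummary(mean=np.zeros(1), covariance=np.eye(1), count=5, ridge=0.0)
        prior = class_prior(["a", "a"], registry=["a", "b"])
        table = class_posterior({"a": g}, prior, np.zeros((2, 1)))
        assert np.all(np.isneginf(table.log_posterior[:, 1]))
        np.testing.assert_allclose(table.posterior[:, 0], 1.0)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_posterior_rows_always_normalize(seed):
    rng = np.random.default_rng(seed)
    conds, prior, pts = _random_bayes_instance(
        rng, n=int(rng.integers(1, 8)), w=int(rng.integers(2, 5)), d=int(rng.integers(1, 4))
    )
    table = class_posterior(conds, prior, pts)
    np.testing.assert_allclose(table.posterior.sum(axis=1), 1.0, atol=1e-9)


class TestSerialization:
    def test_summary_round_trip(self, rng):
        g = fit_gaussian(rng.normal(size=(6, 3)), ridge=1e-4)
        back = GaussianSummary.from_json(g.to_json())
        np.testing.assert_allclose(back.mean, g.mean)
        np.testing.assert_allclose(back.covariance, g.covariance)
        assert back.count == g.count and back.ridge == g.ridge

    def test_posterior_table_round_trip(self, rng):
        conds, prior, pts = _random_bayes_instance(rng, n=4)
        table = class_posterior(conds, prior, pts)
        back = PosteriorTable.from_json(table.to_json())
        np.testing.assert_allclose(back.log_posterior, table.log_posterior)
        assert back.class_ids == [str(c) for c in table.class_ids]
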