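"""Conditional and marginalized likelihoods against independent oracles.

Oracles: scipy.stats.norm for direct density evaluation, scipy
quadrature for the integral of the conditional likelihood against the
patient-level effect prior, and plain Monte Carlo averaging of the
conditional likelihood over sampled patient effects.
"""

import numpy as np
import pytest
from scipy import integrate, stats

from wbam import ModelSpec, conditional_loglik, marginal_loglik


def _peak_aware_quad(density, prior_mean, prior_sd, like_peak, like_sd):
    """Integrate prior x likelihood over one effect, subdividing at both peaks.

    The integrand is a product of two Gaussian bells, so it is only
    non-negligible on the intersection of their supports; integrating
    over that intersection keeps the adaptive rule from missing a spike
    that is narrow relative to the union of the supports.
    """
    lo = max(prior_mean - 12 * prior_sd, like_peak - 12 * like_sd)
    hi = min(prior_mean + 12 * prior_sd, like_peak + 12 * like_sd)
    if lo >= hi:  # disjoint supports: the product is numerically zero
        return 0.0
    pts = sorted(p for p in (prior_mean, like_peak) if lo < p < hi)
    val, _ = integrate.quad(density, lo, hi, points=pts or None, limit=200)
    return val


def _quadrature_marginal(model_id, params, pre, post, is_af):
    """Numerically integrate the conditional density over the effect prior(s)."""
    g = float(is_af)
    sigma = params["sigma"]
    like_sd = sigma / pre  # width of the likelihood as a function of the effect
    if model_id == 2:
        peak = post / pre - g * params["beta_af"]
        return _peak_aware_quad(
            lambda b: stats.norm.pdf(post, (b + g * params["beta_af"]) * pre, sigma)
            * stats.norm.pdf(b, params["mu_ct"], params["sigma_ct"]),
            params["mu_ct"], params["sigma_ct"], peak, like_sd,
        )
    if model_id == 3:
        if g == 0.0:
            return stats.norm.pdf(post, params["beta_ct"] * pre, sigma)
        peak = post / pre - params["beta_ct"]
        return _peak_aware_quad(
            lambda a: stats.norm.pdf(post, (params["beta_ct"] + a) * pre, sigma)
            * stats.norm.pdf(a, params["mu_af"], params["sigma_af"]),
            params["mu_af"], params["sigma_af"], peak, like_sd,
        )
    if model_id == 4:
        if g == 0.0:
            return _peak_aware_quad(
                lambda b: stats.norm.pdf(post, b * pre, sigma)
                * stats.norm.pdf(b, params["mu_ct"], params["sigma_ct"]),
                params["mu_ct"], params["sigma_ct"], post / pre, like_sd,
            )

        def inner(b):
            return _peak_aware_quad(
                lambda a: stats.norm.pdf(post, (b + a) * pre, sigma)
                * stats.norm.pdf(a, params["mu_af"], params["sigma_af"]),
                params["mu_af"], params["sigma_af"], post / pre - b, like_sd,
            ) * stats.norm.pdf(b, params["mu_ct"], params["sigma_ct"])

        # after the inner integral the b-profile has width ~ sqrt of the
        # combined scales; subdivide at both the prior and profile peaks
        profile_sd = np.sqrt(params["sigma_af"] ** 2 + like_sd**2)
        return _peak_aware_quad(
            inner,
            params["mu_ct"], params["sigma_ct"],
            post / pre - params["mu_af"], profile_sd,
        )
    raise ValueError(model_id)


def _random_params(spec, rng):
    params = {}
    for name in spec.param_names:
        if name.startswith("sigma"):
            params[name] = float(rng.uniform(0.002, 0.05))
        else:
            params[name] = float(rng.uniform(0.5, 1.3)) if "ct" in name else float(
                rng.uniform(-0.4, 0.1)
            )
    return params


class TestConditional:
    def test_exact_fit_unit_sigma(self):
        spec = ModelSpec(1)
        ll = conditional_loglik(
            spec, {"beta_ct": 1.0, "beta_af": -0.2, "sigma": 1.0},
            pre=np.array([0.05]), post=np.array([0.8 * 0.05]), is_af=np.array([1.0]),
        )
        assert ll[0] == pytest.approx(np.log(1.0 / np.sqrt(2 * np.pi)), rel=1e-12)

    def test_ct_pairs_ignore_feedback_effect(self):
        spec = ModelSpec(1)
        pre, post = np.array([0.03]), np.array([0.031])
        base = conditional_loglik(
            spec, {"beta_ct": 1.0, "beta_af": -0.2, "sigma": 0.01}, pre, post, np.array([0.0])
        )
        changed = conditional_loglik(
            spec, {"beta_ct": 1.0, "beta_af": 5.0, "sigma": 0.01}, pre, post, np.array([0.0])
        )
        np.testing.assert_array_equal(base, changed)

    def test_matches_normal_density_oracle(self, rng):
        spec = ModelSpec(1)
        for _ in range(20):
            params = {
                "beta_ct": rng.uniform(0.5, 1.5),
                "beta_af": rng.uniform(-0.5, 0.1),
                "sigma": rng.uniform(0.001, 0.1),
            }
            pre = rng.uniform(0.01, 0.1, size=5)
            post = rng.uniform(0.0, 0.1, size=5)
            g = rng.integers(0, 2, size=5).astype(float)
            mine = conditional_loglik(spec, params, pre, post, g)
            oracle = stats.norm.logpdf(
                post, (params["beta_ct"] + g * params["beta_af"]) * pre, params["sigma"]
            )
            np.testing.assert_allclose(mine, oracle, rtol=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            conditional_loglik(
                ModelSpec(1), {"beta_ct": 1.0, "beta_af": 0.0, "sigma": 0.0},
                np.array([0.05]), np.array([0.05]), np.array([0.0]),
            )


class TestMarginal:
    def test_model1_equals_conditional(self, rng):
        spec = ModelSpec(1)
        params = {"beta_ct": 1.05, "beta_af": -0.21, "sigma": 0.01}
        pre = rng.uniform(0.01, 0.1, size=8)
        post = rng.uniform(0.0, 0.1, size=8)
        g = rng.integers(0, 2, size=8).astype(float)
        np.testing.assert_allclose(
            marginal_loglik(spec, params, pre, post, g),
            conditional_loglik(spec, params, pre, post, g),
            rtol=1e-12,
        )

    def test_degenerate_hierarchy_reduces_to_model1(self):
        pre, post, g = np.array([0.04]), np.array([0.035]), np.array([1.0])
        m2 = marginal_loglik(
            ModelSpec(2),
            {"mu_ct": 1.05, "sigma_ct": 0.0, "beta_af": -0.2, "sigma": 0.01},
            pre, post, g,
        )
        m1 = conditional_loglik(
            ModelSpec(1), {"beta_ct": 1.05, "beta_af": -0.2, "sigma": 0.01}, pre, post, g
        )
        np.testing.assert_allclose(m2, m1, rtol=1e-12)

    @pytest.mark.parametrize("model_id", [2, 3, 4])
    @pytest.mark.parametrize("is_af", [0.0, 1.0])
    def test_matches_quadrature_oracle(self, model_id, is_af, rng):
        spec = ModelSpec(model_id)
        for _ in range(5):
            params = _random_params(spec, rng)
            pre = float(rng.uniform(0.01, 0.1))
            post = float(rng.uniform(0.0, 0.12))
            mine = marginal_loglik(
                spec, params, np.array([pre]), np.array([post]), np.array([is_af])
            ).item()
            oracle = _quadrature_marginal(model_id, params, pre, post, is_af)
            assert np.exp(mine) == pytest.approx(oracle, abs=1e-6, rel=1e-6)

    @pytest.mark.parametrize("model_id", [2, 3, 4])
    def test_density_normalizes_over_post(self, model_id, rng):
        spec = ModelSpec(model_id)
        params = _random_params(spec, rng)
        pre = 0.05

        def density(post):
            return np.exp(
                marginal_loglik(
                    spec, params, np.array([pre]), np.array([post]), np.array([1.0])
                )
            ).item()

        total, _ = integrate.quad(density, -1.0, 1.0, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("model_id", [2, 3, 4])
    def test_monte_carlo_consistency_with_conditional(self, model_id):
        """MC average of the conditional likelihood over sampled patient
        effects matches the closed-form marginal within 3 MC standard errors."""
        rng = np.random.default_rng(model_id)
        spec = ModelSpec(model_id)
        params = _random_params(spec, rng)
        pre, post, g = 0.05, 0.042, 1.0
        n_mc = 100_000
        beta_ct = (
            rng.normal(params["mu_ct"], params["sigma_ct"], n_mc)
            if spec.hierarchical_ct
            else np.full(n_mc, params["beta_ct"])
        )
        beta_af = (
            rng.normal(params["mu_af"], params["sigma_af"], n_mc)
            if spec.hierarchical_af
            else np.full(n_mc, params["beta_af"])
        )
        lik = stats.norm.pdf(post, (beta_ct + g * beta_af) * pre, params["sigma"])
        mc_mean = lik.mean()
        mc_se = lik.std(ddof=1) / np.sqrt(n_mc)
        marginal = np.exp(
            marginal_loglik(
                spec, params, np.array([pre]), np.array([post]), np.array([g])
            )
        ).item()
        assert abs(marginal - mc_mean) < 3 * mc_se

    def test_vectorized_draws_match_scalar_calls(self, rng):
        spec = ModelSpec(4)
        theta = np.column_stack(
            [
                rng.uniform(0.8, 1.2, 10),
                rng.uniform(0.001, 0.05, 10),
                rng.uniform(-0.3, 0.0, 10),
                rng.uniform(0.001, 0.05, 10),
                rng.uniform(0.005, 0.02, 10),
            ]
        )
        pre = rng.uniform(0.01, 0.1, 6)
        post = rng.uniform(0.0, 0.1, 6)
        g = rng.integers(0, 2, 6).astype(float)
        matrix = marginal_loglik(spec, theta, pre, post, g)
        assert matrix.shape == (10, 6)
        for s in range(10):
            params = dict(zip(spec.param_names, theta[s]))
            np.testing.assert_allclose(
                matrix[s], marginal_loglik(spec, params, pre, post, g), rtol=1e-12
            )


def test_spec_hierarchy_mapping():
    assert ModelSpec(1).param_names == ("beta_ct", "beta_af", "sigma")
    assert ModelSpec(2).param_names == ("mu_ct", "sigma_ct", "beta_af", "sigma")
    assert ModelSpec(3).param_names == ("beta_ct", "mu_af", "sigma_af", "sigma")
    assert ModelSpec(4).param_names == ("mu_ct", "sigma_ct", "mu_af", "sigma_af", "sigma")
    with pytest.raises(ValueError):
        ModelSpec(5)
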