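"""Zero-inflated beta inference: design validation, gradients, posterior
checks with closed-form anchors, derived quantities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

from gencontrib.simulate import simulate_regression_data
from gencontrib.zib import (
    MCMCSettings,
    ModelSpec,
    _Layout,
    _initial_theta,
    bayes_r2,
    build_design,
    fit_model,
    interaction_pruning,
    make_log_post_and_grad,
    make_log_posterior,
    prob_direction,
    r2_difference,
)

LITE = MCMCSettings(n_steps=200, n_burn=200, thin=1, n_chains=2,
                    target_accept=0.9)


def _sim(beta, zero=None, phi=30.0, n=1500, seed=0, **kw):
    coeffs = dict(beta=beta, phi=phi, **kw)
    if zero is not None:
        coeffs["zero"] = zero
    data, truth = simulate_regression_data(coeffs, n=n, seed=seed,
                                           zero_inflated=zero is not None)
    return data, truth


class TestDesign:
    def test_response_range_validated(self):
        df = pd.DataFrame({"igc": [0.2, 1.2], "parish": ["A", "B"],
                           "sex": ["F", "M"], "birth_cohort": ["c", "c"]})
        with pytest.raises(ValueError, match="0, 1"):
            build_design(df, ModelSpec(proxy=None))

    def test_beta_model_rejects_zeros(self):
        df = pd.DataFrame({"igc": [0.2, 0.0], "parish": ["A", "B"],
                           "sex": ["F", "M"], "birth_cohort": ["c", "c"]})
        with pytest.raises(ValueError, match="positive"):
            build_design(df, ModelSpec(proxy=None, zero_inflated=False))

    def test_interaction_needs_two_parishes(self):
        df = pd.DataFrame({"igc": [0.2, 0.3], "lrs": [1.0, 2.0],
                           "parish": ["A", "A"], "sex": ["F", "M"],
                           "birth_cohort": ["c", "c"]})
        with pytest.raises(ValueError, match="parish"):
            build_design(df, ModelSpec(proxy="lrs", interaction=True))

    def test_gradient_matches_finite_differences(self):
        data, _ = _sim([-2, 0.1, -0.3, 0.2], zero=[0.3, -0.2, 0.1, 0.0],
                       n=200, seed=3, sigma_int_beta=0.2, sigma_int_zero=0.2)
        spec = ModelSpec(response="igc", proxy="proxy")
        design = build_design(data, spec)
        lay = _Layout.make(design, spec)
        f = make_log_post_and_grad(design, lay)
        rng = np.random.default_rng(0)
        theta = _initial_theta(design, lay) + 0.2 * rng.standard_normal(lay.ndim)
        lp, grad = f(theta)
        for i in rng.choice(lay.ndim, size=12, replace=False):
            e = np.zeros(lay.ndim)
            e[i] = 1e-6
            num = (f(theta + e)[0] - f(theta - e)[0]) / 2e-6
            assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-5)

    def test_vectorized_and_scalar_posteriors_agree(self):
        data, _ = _sim([-2, 0.1, 0, 0], zero=[0.3, 0, 0, 0], n=200, seed=4)
        spec = ModelSpec(response="igc", proxy="proxy")
        design = build_design(data, spec)
        lay = _Layout.make(design, spec)
        f_vec = make_log_posterior(design, lay)
        f_grad = make_log_post_and_grad(design, lay)
        rng = np.random.default_rng(1)
        thetas = _initial_theta(design, lay)[None, :] \
            + 0.2 * rng.standard_normal((5, lay.ndim))
        vec_vals = f_vec(thetas)
        for t, v in zip(thetas, vec_vals):
            assert f_grad(t)[0] == pytest.approx(v, rel=1e-10)


class TestProbDirection:
    def test_all_positive(self):
        p, cls = prob_direction(np.abs(np.random.default_rng(0).normal(1, 0.1, 500)))
        assert p == 1.0 and cls == "highly significant"

    def test_half_and_half(self):
        draws = np.concatenate([np.full(100, 0.5), np.full(100, -0.5),
                                [0.1]])
        p, cls = prob_direction(draws)
        assert p == pytest.approx(0.5, abs=0.01)
        assert cls == "not significant"

    def test_trend_band(self):
        draws = np.concatenate([np.full(96, 1.0), np.full(4, -1.0)])
        p, cls = prob_direction(draws)
        assert p == 0.96 and cls == "trend"

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            prob_direction(np.ones(50))

    def test_degenerate_zero_draws(self):
        with pytest.raises(ValueError):
            prob_direction(np.zeros(200))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_to_odd_monotone_reparameterization(self, seed):
        rng = np.random.default_rng(seed)
        draws = rng.normal(rng.normal(), 1.0, 300)
        if np.median(draws) == 0:
            return
        p1, _ = prob_direction(draws)
        p2, _ = prob_direction(draws**3)  # sign-preserving monotone map
        assert p1 == p2


@pytest.fixture(scope="module")
def anchored_fit():
    """Null-model fit on data with a known 30% zero mass and flat mean."""
    data, _ = _sim([logit(0.15), 0, 0, 0], zero=[logit(0.3), 0, 0, 0],
                   phi=40.0, n=3000, seed=8)
    spec = ModelSpec(response="igc", proxy=None, zero_inflated=True)
    return data, fit_model(data, spec, LITE, seed=0)


class TestFit:
    def test_zero_intercept_matches_bernoulli_mle(self, anchored_fit):
        data, fit = anchored_fit
        mle = logit((data.igc == 0).mean())
        med = np.median(fit.draws_of("zi_intercept"))
        assert med == pytest.approx(mle, abs=0.15)

    def test_beta_intercept_matches_mean_of_nonzero(self, anchored_fit):
        data, fit = anchored_fit
        target = logit(data.igc[data.igc > 0].mean())
        assert np.median(fit.draws_of("b_intercept")) == pytest.approx(
            target, abs=0.1)

    def test_rhat_reported_for_every_parameter(self, anchored_fit):
        _, fit = anchored_fit
        assert set(fit.rhat.index) == set(fit.param_names)
        assert fit.rhat.notna().all()
        s = fit.summary()
        assert set(s.parameter) == set(fit.param_names)

    def test_reproducible_given_seed(self):
        data, _ = _sim([-2, 0.05, 0, 0], zero=[0.2, 0, 0, 0], n=400, seed=1)
        spec = ModelSpec(response="igc", proxy="proxy")
        tiny = MCMCSettings(n_steps=60, n_burn=60, thin=1, n_chains=2)
        f1 = fit_model(data, spec, tiny, seed=11)
        f2 = fit_model(data, spec, tiny, seed=11)
        assert np.array_equal(f1.chain, f2.chain)


class TestBayesR2:
    def test_near_zero_for_intercept_only(self, anchored_fit):
        _, fit = anchored_fit
        assert bayes_r2(fit).median < 0.05

    def test_mixture_and_draws_methods_agree(self, anchored_fit):
        _, fit = anchored_fit
        assert bayes_r2(fit).median == pytest.approx(
            bayes_r2(fit, method="draws").median, abs=0.02)

    def test_affine_rescaling_invariance(self):
        """Rescaling the proxy leaves R² unchanged (slope absorbs it)."""
        data, gt = _sim([-2, 0.2, 0, 0], zero=[0.5, -0.3, 0, 0], n=1500,
                        seed=7)
        scaled = data.copy()
        scaled["proxy"] = scaled["proxy"] * 10.0
        spec = ModelSpec(response="igc", proxy="proxy")
        r2a = bayes_r2(fit_model(data, spec, LITE, seed=4)).median
        r2b = bayes_r2(fit_model(scaled, spec, LITE, seed=4)).median
        assert r2a == pytest.approx(r2b, abs=0.04)


class TestR2Difference:
    def test_identity_fit_centred_on_zero(self, anchored_fit):
        _, fit = anchored_fit
        d = r2_difference(fit, fit)
        assert d["mode"] == pytest.approx(0.0, abs=1e-9)
        assert not d["significant"]

    def test_different_n_rejected(self, anchored_fit):
        data, fit = anchored_fit
        small = fit_model(data.iloc[:500],
                          ModelSpec(response="igc", proxy=None),
                          MCMCSettings(n_steps=60, n_burn=60, thin=1,
                                       n_chains=2), seed=0)
        with pytest.raises(ValueError, match="different data"):
            r2_difference(fit, small)

    def test_signal_vs_null_significant(self):
        data, gt = _sim([-2.5, 0.2, 0, 0], zero=[1.5, -0.6, 0, 0], n=2500,
                        seed=9)
        fit_signal = fit_model(data, gt["spec"], LITE, seed=5)
        fit_null = fit_model(
            data, ModelSpec(response="igc", proxy=None), LITE, seed=5)
        d = r2_difference(fit_signal, fit_null)
        assert d["significant"] and d["mode"] > 0


class TestInteractionPruning:
    def test_zero_interaction_dropped(self):
        data, gt = _sim([-2, 0.1, -0.3, 0.2], zero=[0.5, -0.2, 0.2, -0.1],
                        n=1500, seed=10)
        spec, fit = interaction_pruning(
            data, ModelSpec(response="igc", proxy="proxy"), LITE, seed=1)
        assert not spec.interaction
        assert not any(":parish[" in n for n in fit.param_names)

    def test_strong_interaction_retained(self):
        data, gt = _sim([-2, 0.1, -0.3, 0.2], zero=[0.5, -0.2, 0.2, -0.1],
                        n=2000, seed=11)
        # overwrite the response with a strong sex-by-parish shift in both parts
        from gencontrib.zib import simulate_response
        shift = dict(beta=[-2, 0.1, -0.3, 0.2, 1.2],
                     zero=[0.5, -0.2, 0.2, -0.1, 1.5], phi=30.0)
        spec_gen = ModelSpec(response="igc", proxy="proxy", interaction=True)
        data2, _ = simulate_response(data, spec_gen, shift, seed=12)
        spec, fit = interaction_pruning(
            data2, ModelSpec(response="igc", proxy="proxy"), LITE, seed=2)
        assert spec.interaction

    def test_single_parish_errors_with_term_name(self):
        data, _ = _sim([-2, 0.1, 0, 0], zero=[0.5, 0, 0, 0], n=300, seed=12)
        data["parish"] = "A"
        data["birth_cohort"] = "A:" + data["birth_cohort"].str[2:]
        with pytest.raises(ValueError, match="interaction"):
            interaction_pruning(data, ModelSpec(response="igc", proxy="proxy"),
                                LITE, seed=0)
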