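"""Posterior engine: likelihoods, sampling correctness against
closed-form / brute-force oracles, and summary utilities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, gammaln

from pitchsync.bglmm import (
    Continuous,
    Factor,
    ModelSpec,
    PriorSet,
    RandomEffects,
    bayes_r2,
    build_model,
    contrast,
    finite_diff_slope,
    half_split_contrast,
    hdi,
    icc,
    log_posterior,
    marginal_predictions,
    pd_of_draws,
    pd_to_p_and_er,
    sample_posterior,
    summarize_draws,
)

from conftest import fake_draws


# ---------------------------------------------------------------------------
# log posterior


class TestLogPosterior:
    def test_binomial_closed_form(self):
        # y=20 of n=40 at logit(p)=0: ll = log C(40,20) + 40 log(1/2); the
        # intercept prior is centered at the data-derived logit(0.5)=0, so
        # the prior adds nothing at theta=0
        df = pd.DataFrame({"y": [20], "n": [40]})
        spec = ModelSpec(family="binomial_logit", response="y", trials="n")
        model = build_model(spec, df)
        lp = log_posterior(model, params=np.zeros(model.n_params))
        expected = gammaln(41) - 2 * gammaln(21) + 40 * np.log(0.5)
        assert lp == pytest.approx(expected, abs=1e-10)

    def test_gamma_loglik_matches_scipy(self):
        rng = np.random.default_rng(0)
        y = rng.gamma(3.0, 0.5, 25)
        df = pd.DataFrame({"y": y})
        spec = ModelSpec(family="gamma_log", response="y")
        model = build_model(spec, df)
        th = np.zeros(model.n_params)
        icpt = np.log(y.mean())
        th[0] = icpt  # intercept at its prior center -> zero prior mass there
        log_shape = 0.7
        th[model.slices["log_shape"]] = log_shape
        alpha, mu = np.exp(log_shape), np.exp(icpt)
        oracle = stats.gamma.logpdf(y, a=alpha, scale=mu / alpha).sum()
        prior = -0.5 * ((log_shape - 0.0) / 1.5) ** 2
        assert log_posterior(model, params=th) == pytest.approx(oracle + prior, abs=1e-8)

    def test_gaussian_zero_residual_limit(self):
        # residual sd fixed to zero with known SEs: must stay finite
        df = pd.DataFrame({"y": [1.0, 2.0], "se": [0.5, 0.5]})
        spec = ModelSpec(
            family="gaussian_identity", response="y", se_col="se", estimate_sigma=False
        )
        model = build_model(spec, df)
        th = np.zeros(model.n_params)
        th[0] = 1.5
        assert np.isfinite(log_posterior(model, params=th))

    def test_gradient_matches_finite_differences(self):
        # joint check across all parameter kinds (factor, smooth, monotonic,
        # random, gamma shape)
        from pitchsync.bglmm.model import Interaction, Monotonic, Smooth
        from pitchsync.bglmm.model import _logp_grad

        rng = np.random.default_rng(3)
        n = 60
        df = pd.DataFrame(
            {
                "y": rng.gamma(2.0, 1.0, n),
                "x": rng.normal(size=n),
                "g": rng.choice(["a", "b", "c"], n),
                "lev": rng.integers(0, 4, n),
                "subj": rng.choice([f"s{i}" for i in range(8)], n),
            }
        )
        spec = ModelSpec(
            family="gamma_log",
            response="y",
            terms=[Factor("g"), Smooth("x", k=6), Monotonic("lev")],
            random=[RandomEffects("subj", slopes=(Continuous("x"),))],
        )
        model = build_model(spec, df)
        th = 0.3 * rng.standard_normal(model.n_params)
        lp, grad = _logp_grad(model, th)
        num = np.zeros_like(th)
        eps = 1e-6
        for i in range(len(th)):
            tp, tm = th.copy(), th.copy()
            tp[i] += eps
            tm[i] -= eps
            num[i] = (_logp_grad(model, tp)[0] - _logp_grad(model, tm)[0]) / (2 * eps)
        np.testing.assert_allclose(grad, num, rtol=1e-4, atol=1e-5)


# ---------------------------------------------------------------------------
# sampling against oracles


class TestSampling:
    def test_conjugate_normal_posterior_mean(self):
        # known observation SD, residual fixed at 0: the intercept posterior
        # is conjugate; precision-weighted mean is the oracle
        rng = np.random.default_rng(1)
        n, se = 30, 1.0
        y = rng.normal(2.0, se, n)
        df = pd.DataFrame({"y": y, "se": np.full(n, se)})
        spec = ModelSpec(
            family="gaussian_identity",
            response="y",
            se_col="se",
            estimate_sigma=False,
            priors=PriorSet(intercept_scale=1.0),
        )
        model = build_model(spec, df)
        draws = sample_posterior(model, chains=4, iterations=1000, seed=3)
        prior_loc, prior_sd = model.prior_loc[0], 1.0
        closed = (prior_loc / prior_sd**2 + y.sum() / se**2) / (
            1 / prior_sd**2 + n / se**2
        )
        assert draws.param("Intercept").mean() == pytest.approx(closed, abs=0.01)
        assert draws.diagnostics["rhat"].max() < 1.01  # well-specified run

    def test_logistic_posterior_near_grid_mle(self):
        rng = np.random.default_rng(7)
        n = 150
        x = rng.normal(size=n)
        p = expit(-0.4 + 0.9 * x)
        y = rng.binomial(10, p)
        df = pd.DataFrame({"y": y, "n": 10, "x": x})
        spec = ModelSpec(
            family="binomial_logit",
            response="y",
            trials="n",
            terms=[Continuous("x", standardize=False)],
        )

        def nll(b0, b1):
            eta = b0 + b1 * x
            return -(y * eta - 10 * np.logaddexp(0, eta)).sum()

        # coarse-to-fine brute-force grid search (independent oracle)
        b0s = np.linspace(-2, 2, 81)
        b1s = np.linspace(-2, 2, 81)
        for _ in range(3):
            grid = np.array([[nll(a, b) for b in b1s] for a in b0s])
            i, j = np.unravel_index(np.argmin(grid), grid.shape)
            w0 = b0s[1] - b0s[0]
            b0s = np.linspace(b0s[i] - w0, b0s[i] + w0, 41)
            w1 = b1s[1] - b1s[0]
            b1s = np.linspace(b1s[j] - w1, b1s[j] + w1, 41)
        mle = (b0s[20], b1s[20])
        draws = sample_posterior(spec, df, chains=4, iterations=1000, seed=9)
        assert np.median(draws.param("Intercept")) == pytest.approx(mle[0], abs=0.05)
        assert np.median(draws.param("x")) == pytest.approx(mle[1], abs=0.05)

    def test_identical_seed_identical_draws(self):
        df = pd.DataFrame({"y": [3, 5, 7, 9], "n": 20})
        spec = ModelSpec(family="binomial_logit", response="y", trials="n")
        a = sample_posterior(spec, df, chains=2, iterations=100, seed=5)
        b = sample_posterior(spec, df, chains=2, iterations=100, seed=5)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_known_se_inflation_attenuates_effects(self):
        rng = np.random.default_rng(4)
        n = 30
        x = rng.normal(size=n)
        y = 2.0 * x + rng.normal(0, 0.5, n)
        out = {}
        for se in (0.5, 5.0):
            df = pd.DataFrame({"y": y, "x": x, "se": np.full(n, se)})
            spec = ModelSpec(
                family="gaussian_identity",
                response="y",
                se_col="se",
                estimate_sigma=False,
                terms=[Continuous("x", standardize=False)],
            )
            d = sample_posterior(spec, df, chains=2, iterations=600, seed=11)
            out[se] = np.abs(d.param("x").mean())
        assert out[5.0] < out[0.5]  # shrinks toward the prior location 0

    def test_reparameterization_invariance_of_fitted_values(self):
        rng = np.random.default_rng(8)
        g = np.repeat(["a", "b", "c"], 25)
        p_true = {"a": 0.3, "b": 0.5, "c": 0.65}
        y = rng.binomial(20, [p_true[v] for v in g])
        df = pd.DataFrame({"y": y, "n": 20, "g": g})
        grid = pd.DataFrame({"g": ["a", "b", "c"], "trials": 1})
        fits = {}
        for coding in ("orthonormal", "treatment"):
            spec = ModelSpec(
                family="binomial_logit",
                response="y",
                trials="n",
                terms=[Factor("g", coding=coding)],
            )
            d = sample_posterior(spec, df, chains=2, iterations=800, seed=13)
            fits[coding] = marginal_predictions(d, grid).mean(axis=0)
        np.testing.assert_allclose(fits["orthonormal"], fits["treatment"], atol=0.02)


# ---------------------------------------------------------------------------
# summaries


class TestPd:
    @pytest.mark.parametrize(
        "draws,expected",
        [([1, 2, 3], 1.0), ([-2, -1, 1, 2], 0.5), ([-1, 1, 2, 3], 0.75)],
    )
    def test_examples(self, draws, expected):
        assert pd_of_draws(draws) == pytest.approx(expected, abs=1e-15)

    def test_zeros_split_evenly(self):
        assert pd_of_draws([0.0, 0.0, 1.0, -1.0]) == 0.5

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pd_of_draws([])

    def test_p_and_er(self):
        p, er = pd_to_p_and_er(0.975)
        assert p == pytest.approx(0.05, abs=1e-12)
        assert er == pytest.approx(39.0, abs=1e-9)
        assert pd_to_p_and_er(0.5) == (1.0, 1.0)
        assert pd_to_p_and_er(1.0)[1] == np.inf
        with pytest.raises(ValueError):
            pd_to_p_and_er(0.3)


class TestHdi:
    def test_full_mass_is_range(self):
        x = np.array([3.0, -1.0, 2.0])
        assert hdi(x, 1.0) == (-1.0, 3.0)

    def test_point_mass(self):
        assert hdi(np.full(50, 2.5), 0.9) == (2.5, 2.5)

    def test_matches_exhaustive_window_search(self):
        rng = np.random.default_rng(123)
        x = rng.standard_normal(5000)
        for mass in (0.66, 0.90, 0.95):
            lo, hi = hdi(x, mass)
            xs = np.sort(x)
            w = int(np.ceil(mass * len(xs)))
            best = None
            for i in range(len(xs) - w + 1):  # brute force over all windows
                width = xs[i + w - 1] - xs[i]
                if best is None or width < best[0]:
                    best = (width, xs[i], xs[i + w - 1])
            assert (lo, hi) == (best[1], best[2])

    def test_nesting(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(4000)
        s = summarize_draws(x)
        assert s.hdi66[0] >= s.hdi90[0] >= s.hdi95[0]
        assert s.hdi66[1] <= s.hdi90[1] <= s.hdi95[1]


# ---------------------------------------------------------------------------
# predictions and derived quantities


def _gaussian_line_model():
    x = np.linspace(-1, 1, 21)
    df = pd.DataFrame({"y": 0.5 + 1.7 * x, "x": x})
    spec = ModelSpec(
        family="gaussian_identity",
        response="y",
        terms=[Continuous("x", standardize=False)],
    )
    model = build_model(spec, df)
    th = np.zeros(model.n_params)
    th[model.param_index("Intercept")] = 0.5
    th[model.param_index("x")] = 1.7
    return model, th


class TestPredictions:
    def test_null_binomial_predicts_half_of_trials(self):
        df = pd.DataFrame({"y": [10, 20, 30], "n": 40, "x": [0.1, 0.5, 0.9]})
        spec = ModelSpec(
            family="binomial_logit", response="y", trials="n", terms=[Continuous("x")]
        )
        model = build_model(spec, df)
        draws = fake_draws(model, np.zeros((4, model.n_params)))
        grid = pd.DataFrame({"x": [0.2, 0.8], "trials": [40, 40]})
        preds = marginal_predictions(draws, grid)
        np.testing.assert_allclose(preds, 20.0, atol=1e-12)

    def test_contrast_identities(self):
        a = np.random.default_rng(0).normal(size=(50, 3))
        s = contrast(a, a)
        assert s.median == 0.0 and s.pd == 0.5
        s2 = contrast(a + 1.0, a)
        assert s2.median == pytest.approx(1.0, abs=1e-12)
        assert s2.pd == 1.0
        with pytest.raises(ValueError):
            contrast(a, a[:10])

    def test_intercept_shift_moves_predictions_monotonically(self):
        df = pd.DataFrame({"y": [10, 20], "n": 40})
        spec = ModelSpec(family="binomial_logit", response="y", trials="n")
        model = build_model(spec, df)
        lo = fake_draws(model, [[-0.5]])
        hi = fake_draws(model, [[0.5]])
        g = pd.DataFrame({"trials": [40]})
        assert (marginal_predictions(hi, g) > marginal_predictions(lo, g)).all()

    def test_linear_slope_is_exact(self):
        model, th = _gaussian_line_model()
        draws = fake_draws(model, [th, th])
        grid = pd.DataFrame({"x": [-0.5, 0.0, 0.5]})
        slopes, flags = finite_diff_slope(draws, "x", grid)
        np.testing.assert_allclose(slopes, 1.7, atol=1e-8)
        assert not flags.any()

    def test_logistic_slope_at_linear_predictor_zero(self):
        # d(count)/dx at eta=0 is n * beta / 4
        df = pd.DataFrame({"y": [20, 20], "n": 40, "x": [-1.0, 1.0]})
        spec = ModelSpec(
            family="binomial_logit",
            response="y",
            trials="n",
            terms=[Continuous("x", standardize=False)],
        )
        model = build_model(spec, df)
        th = np.zeros(model.n_params)
        th[model.param_index("x")] = 0.3
        draws = fake_draws(model, [th])
        grid = pd.DataFrame({"x": [0.0], "trials": [40]})
        slopes, _ = finite_diff_slope(draws, "x", grid, h=1e-4)
        assert slopes[0, 0] == pytest.approx(40 * 0.3 / 4, rel=1e-6)

    def test_support_edge_flags_one_sided(self):
        model, th = _gaussian_line_model()
        draws = fake_draws(model, [th])
        slopes, flags = finite_diff_slope(draws, "x", pd.DataFrame({"x": [-1.0]}))
        assert flags[0]
        np.testing.assert_allclose(slopes, 1.7, atol=1e-8)

    def test_half_split_flat_and_increasing(self):
        model, th = _gaussian_line_model()
        flat = th.copy()
        flat[model.param_index("x")] = 0.0
        s_flat = half_split_contrast(fake_draws(model, [flat, flat]), "x")
        assert s_flat.median == pytest.approx(0.0, abs=1e-12)
        assert s_flat.pd == 0.5
        s_up = half_split_contrast(fake_draws(model, [th, th]), "x")
        assert s_up.median > 0 and s_up.pd == 1.0
        # symmetric predictor: mean and median split agree
        s_mean = half_split_contrast(fake_draws(model, [th, th]), "x", split="mean")
        assert s_mean.median == pytest.approx(s_up.median, abs=1e-12)


class TestR2AndIcc:
    def _gaussian_group_model(self, log_sigma, log_d):
        rng = np.random.default_rng(2)
        n_g, per = 10, 5
        df = pd.DataFrame(
            {
                "y": rng.normal(size=n_g * per),
                "g": np.repeat([f"g{i}" for i in range(n_g)], per),
            }
        )
        spec = ModelSpec(
            family="gaussian_identity", response="y", random=[RandomEffects("g")]
        )
        model = build_model(spec, df)
        th = np.zeros(model.n_params)
        th[model.param_index("log_sigma")] = log_sigma
        th[model.slices[("rand", 0, "log_d")]] = log_d
        return model, th

    def test_r2_limits(self):
        model, th = _gaussian_line_model()
        th2 = th.copy()
        th2[model.param_index("log_sigma")] = -10.0  # near-zero residual
        r2 = bayes_r2(fake_draws(model, [th2, th2]))
        assert r2.median == pytest.approx(1.0, abs=1e-4)
        th3 = np.zeros(model.n_params)  # no fitted variance, sigma = 1
        r2_zero = bayes_r2(fake_draws(model, [th3, th3]))
        assert r2_zero.median == pytest.approx(0.0, abs=1e-12)

    def test_icc_half_when_group_equals_residual_variance(self):
        model, th = self._gaussian_group_model(log_sigma=0.0, log_d=0.0)
        val = icc(fake_draws(model, [th] * 10), "g", n_sim=400, seed=1)
        assert val.median == pytest.approx(0.5, abs=0.08)

    def test_icc_zero_without_group_variance(self):
        model, th = self._gaussian_group_model(log_sigma=0.0, log_d=np.log(1e-6))
        val = icc(fake_draws(model, [th] * 10), "g", n_sim=400, seed=1)
        assert abs(val.median) < 0.05
        assert -0.1 <= val.median <= 1.0

    def test_unknown_grouping_errors(self):
        model, th = self._gaussian_group_model(0.0, 0.0)
        with pytest.raises(ValueError, match="grouped"):
            icc(fake_draws(model, [th]), "nonexistent")
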