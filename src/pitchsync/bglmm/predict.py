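"""Posterior predictions and derived effect summaries on the response
scale: marginal means, contrasts, finite-difference slopes, predictor
half-split contrasts, Bayesian R², and the intra-class correlation via
variance decomposition of the posterior predictive distribution."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import BuiltModel
from .sampler import PosteriorDraws
from .summaries import SummaryStats, summarize_draws

__all__ = [
    "eta_draws",
    "marginal_predictions",
    "contrast",
    "finite_diff_slope",
    "half_split_contrast",
    "bayes_r2",
    "icc",
]


def _theta_matrix(draws: PosteriorDraws, max_draws: int | None) -> np.ndarray:
    return draws.thin(max_draws) if max_draws else draws.stacked()


def eta_draws(
    model: BuiltModel,
    theta_mat: np.ndarray,
    design: dict | None = None,
    include_random: bool = False,
) -> np.ndarray:
    """Linear predictor for a matrix of parameter draws; (n_draws, n_rows).

    ``include_random`` only applies to the observed design (group effects
    are zero, i.e. population-level, on new prediction grids).
    """
    observed = design is None
    if observed:
        design = {
            "X": model.X,
            "smooth_B": [s.B for s in model.smooths],
            "mono_levels": [m.levels(model.data) for m in model.monos],
        }
    th = np.atleast_2d(theta_mat)
    eta = th[:, model.slices["beta"]] @ design["X"].T
    for i, s in enumerate(model.smooths):
        tau = np.exp(th[:, model.slices[("smooth", i, "log_tau")]])  # (nd, 1)
        z = th[:, model.slices[("smooth", i, "z")]]
        eta = eta + tau * (z @ design["smooth_B"][i].T)
    for i, m in enumerate(model.monos):
        beta_m = th[:, model.slices[("mono", i, "beta")]]  # (nd, 1)
        u = th[:, model.slices[("mono", i, "u")]]
        w = np.concatenate([u, np.zeros((len(th), 1))], axis=1)
        w = w - w.max(axis=1, keepdims=True)
        e = np.exp(w)
        zeta = e / e.sum(axis=1, keepdims=True)
        cum = np.concatenate([np.zeros((len(th), 1)), np.cumsum(zeta, axis=1)], axis=1)
        eta = eta + beta_m * cum[:, design["mono_levels"][i]]
    if include_random and observed:
        for i, rb in enumerate(model.randoms):
            b = _rand_b_draws(model, th, i)  # (nd, J, q)
            eta = eta + np.einsum("nik,ik->ni", b[:, rb.codes, :], rb.W)
    return eta


def _rand_A_draws(model, th, i):
    rb = model.randoms[i]
    q = rb.q
    nd = len(th)
    A = np.zeros((nd, q, q))
    d = np.exp(th[:, model.slices[("rand", i, "log_d")]])
    A[:, np.arange(q), np.arange(q)] = d
    if q > 1:
        rows, cols = np.tril_indices(q, -1)
        A[:, rows, cols] = th[:, model.slices[("rand", i, "off")]]
    return A


def _rand_b_draws(model, th, i):
    rb = model.randoms[i]
    z = th[:, model.slices[("rand", i, "z")]].reshape(len(th), rb.J, rb.q)
    A = _rand_A_draws(model, th, i)
    return np.einsum("nqk,njk->njq", A, z)


def marginal_predictions(
    draws: PosteriorDraws,
    grid: pd.DataFrame,
    max_draws: int | None = None,
    response_scale: bool = True,
) -> np.ndarray:
    """Expected response per draw and grid row; (n_draws, n_rows).

    Group (random) effects are marginalized by setting them to zero
    (population-level prediction).  Covariates missing from the grid are
    held at their reference/mean values.  For the binomial family the
    response scale is the expected count (trials taken from a ``trials``
    column of the grid, else the model's average trials).
    """
    model = draws.model
    th = _theta_matrix(draws, max_draws)
    design = model.design_at(grid)
    eta = eta_draws(model, th, design=design)
    if not response_scale:
        return eta
    mu = model.inverse_link(eta)
    if model.spec.family == "binomial_logit":
        if "trials" in grid.columns:
            n = np.asarray(grid["trials"], dtype=float)
        elif isinstance(model.spec.trials, str) and model.spec.trials in grid.columns:
            n = np.asarray(grid[model.spec.trials], dtype=float)
        else:
            n = model.default_trials()
        mu = mu * n
    return mu


def contrast(preds_a: np.ndarray, preds_b: np.ndarray) -> SummaryStats:
    """Summary of the per-draw difference A - B.

    Inputs are per-draw predictions, either one value per draw or a
    (draws, rows) matrix; matrices are averaged over rows per draw
    (marginal-mean contrast)."""
    a = np.asarray(preds_a, dtype=float)
    b = np.asarray(preds_b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"draw count mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.ndim > 1:
        a = a.mean(axis=tuple(range(1, a.ndim)))
    if b.ndim > 1:
        b = b.mean(axis=tuple(range(1, b.ndim)))
    return summarize_draws(a - b)


def finite_diff_slope(
    draws: PosteriorDraws,
    predictor: str,
    grid: pd.DataFrame,
    h: float | None = None,
    max_draws: int | None = None,
    response_scale: bool = True,
):
    """Local slopes of the posterior predictions with respect to a
    continuous predictor, by central finite differences.

    ``h`` defaults to 1% of the predictor's observed range.  Where
    x ± h/2 would leave the observed support the difference degrades to a
    one-sided one and the corresponding flag is set.

    Returns ``(slopes, one_sided)``: slopes is (n_draws, n_rows).
    """
    model = draws.model
    x_obs = np.asarray(model.data[predictor], dtype=float)
    lo_s, hi_s = float(x_obs.min()), float(x_obs.max())
    if h is None:
        h = 0.01 * (hi_s - lo_s)
    if h <= 0:
        raise ValueError("h must be positive")
    grid = model.complete_grid(grid)
    x0 = np.asarray(grid[predictor], dtype=float)
    lo = x0 - h / 2
    hi = x0 + h / 2
    one_sided = (lo < lo_s) | (hi > hi_s)
    lo = np.where(x0 - h / 2 < lo_s, x0, x0 - h / 2)
    hi = np.where(x0 + h / 2 > hi_s, x0, x0 + h / 2)
    denom = hi - lo
    if np.any(denom <= 0):
        raise ValueError(
            f"grid point(s) of {predictor!r} leave no room for a finite difference"
        )
    grid_lo = grid.copy()
    grid_lo[predictor] = lo
    grid_hi = grid.copy()
    grid_hi[predictor] = hi
    p_lo = marginal_predictions(draws, grid_lo, max_draws, response_scale)
    p_hi = marginal_predictions(draws, grid_hi, max_draws, response_scale)
    return (p_hi - p_lo) / denom, one_sided


def half_split_contrast(
    draws: PosteriorDraws,
    predictor: str,
    split: str = "median",
    grid: pd.DataFrame | None = None,
    max_draws: int | None = None,
) -> SummaryStats:
    """Average response-scale prediction over grid rows with the predictor
    above its split value minus the average below (per draw)."""
    model = draws.model
    if grid is None:
        grid = model.data
    x_obs = np.asarray(model.data[predictor], dtype=float)
    if split == "median":
        s = float(np.median(x_obs))
    elif split == "mean":
        s = float(np.mean(x_obs))
    else:
        raise ValueError(f"split must be 'median' or 'mean', got {split!r}")
    x = np.asarray(grid[predictor], dtype=float)
    upper = x > s
    lower = ~upper
    if upper.sum() == 0 or lower.sum() == 0:
        raise ValueError(f"empty half at split {s:g} of {predictor!r}")
    preds = marginal_predictions(draws, grid, max_draws)
    diff = preds[:, upper].mean(axis=1) - preds[:, lower].mean(axis=1)
    return summarize_draws(diff)


def _residual_variance(model: BuiltModel, th, mu):
    """Model residual variance on the response scale, per draw x obs."""
    fam = model.spec.family
    if fam == "binomial_logit":
        n = model.trials
        p = mu / n
        return n * p * (1 - p)
    if fam == "gaussian_identity":
        se2 = np.mean(model.se**2) if model.se is not None else 0.0
        if model.spec.estimate_sigma:
            sigma2 = np.exp(2 * th[:, model.slices["log_sigma"]])
        else:
            sigma2 = np.zeros((len(th), 1))
        return sigma2 + se2 + np.zeros_like(mu)
    alpha = np.exp(th[:, model.slices["log_shape"]])
    return mu**2 / alpha


def bayes_r2(draws: PosteriorDraws, max_draws: int | None = 1000) -> SummaryStats:
    """Bayesian R²: per draw, var(fit) / (var(fit) + var(residual)) on the
    response scale, with fits including the group effects."""
    model = draws.model
    th = _theta_matrix(draws, max_draws)
    eta = eta_draws(model, th, include_random=True)
    mu = model.inverse_link(eta)
    if model.spec.family == "binomial_logit":
        mu = mu * model.trials
    var_fit = mu.var(axis=1)
    var_res = _residual_variance(model, th, mu).mean(axis=1)
    total = var_fit + var_res
    if np.all(total == 0):
        raise ValueError("zero total variance; R2 undefined")
    return summarize_draws(var_fit / total)


def _ppd_sample(model, rng, mu, th_row):
    fam = model.spec.family
    if fam == "binomial_logit":
        n = model.trials
        return rng.binomial(np.broadcast_to(n, mu.shape).astype(int), mu / n)
    if fam == "gaussian_identity":
        se2 = model.se**2 if model.se is not None else 0.0
        sigma2 = (
            np.exp(2 * th_row[model.slices["log_sigma"]][0])
            if model.spec.estimate_sigma
            else 0.0
        )
        return mu + rng.standard_normal(mu.shape) * np.sqrt(sigma2 + se2)
    alpha = np.exp(th_row[model.slices["log_shape"]][0])
    return rng.gamma(alpha, mu / alpha)


def icc(
    draws: PosteriorDraws,
    grouping: str,
    n_sim: int = 80,
    max_draws: int | None = 200,
    seed: int | None = None,
) -> SummaryStats:
    """Intra-class correlation via variance decomposition of the posterior
    predictive distribution.

    Per posterior draw, the predictive distribution over the observed
    design is simulated twice -- once with fresh group effects drawn from
    the fitted group covariance, once with group effects zeroed -- and the
    ICC is the share of predictive variance the grouping accounts for.
    Monte-Carlo error can push individual values slightly below zero.
    """
    model = draws.model
    block_idx = None
    for i, rb in enumerate(model.randoms):
        if rb.group == grouping:
            block_idx = i
    if block_idx is None:
        raise ValueError(f"model has no random term grouped by {grouping!r}")
    rb = model.randoms[block_idx]
    th = _theta_matrix(draws, max_draws)
    rng = np.random.default_rng(draws.seed + 202 if seed is None else seed)
    eta_fixed = eta_draws(model, th, include_random=False)
    mu_kind = model.spec.family
    vals = np.empty(len(th))
    A = _rand_A_draws(model, th, block_idx)
    for n_i in range(len(th)):
        eps = rng.standard_normal((n_sim, rb.q))
        b_sim = eps @ A[n_i].T  # (n_sim, q): one fresh group effect per replicate
        eta_g = eta_fixed[n_i][None, :] + b_sim @ rb.W.T  # (n_sim, n_obs)
        mu_g = model.inverse_link(eta_g)
        mu_0 = model.inverse_link(np.broadcast_to(eta_fixed[n_i], eta_g.shape))
        if mu_kind == "binomial_logit":
            mu_g = mu_g * model.trials
            mu_0 = mu_0 * model.trials
            p_g = mu_g / model.trials
            p_0 = mu_0 / model.trials
            y_g = rng.binomial(np.broadcast_to(model.trials, p_g.shape).astype(int), p_g)
            y_0 = rng.binomial(np.broadcast_to(model.trials, p_0.shape).astype(int), p_0)
        else:
            y_g = _ppd_sample(model, rng, mu_g, th[n_i])
            y_0 = _ppd_sample(model, rng, mu_0, th[n_i])
        v_tot = y_g.var()
        v_no = y_0.var()
        vals[n_i] = (v_tot - v_no) / v_tot if v_tot > 0 else 0.0
    return summarize_draws(vals)
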