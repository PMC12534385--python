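"""Model specification, design building, and the joint log posterior.

The linear predictor is assembled from typed terms; every term is linear
in its coefficients, so the gradient of the log posterior is available in
closed form (used by the HMC sampler).  Parameterization:

* fixed/contrast/linear-smooth coefficients: unconstrained, Gaussian priors;
* penalized smooth blocks: reparameterized to an identity penalty, with
  non-centered coefficients z ~ N(0, 1) scaled by a half-normal tau;
* monotonic ordinal effects: scale coefficient times the cumulative sum of
  a simplex, the simplex parameterized by a pinned softmax with an exact
  Dirichlet prior (Jacobian included);
* correlated group-level effects: non-centered, b_j = A z_j with A the
  Cholesky factor of the covariance, half-normal priors on its diagonal
  and Gaussian priors on the off-diagonal entries;
* positive scale parameters sampled on the log scale (Jacobians included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, psi

from .design import orthonormal_contrasts, tprs_basis

__all__ = [
    "Factor",
    "Continuous",
    "Interaction",
    "Smooth",
    "Monotonic",
    "RandomEffects",
    "PriorSet",
    "ModelSpec",
    "BuiltModel",
    "build_model",
    "log_posterior",
]

FAMILIES = ("binomial_logit", "gaussian_identity", "gamma_log")


# ---------------------------------------------------------------------------
# term vocabulary


@dataclass(frozen=True)
class Factor:
    name: str
    coding: str = "orthonormal"  # or "treatment"


@dataclass(frozen=True)
class Continuous:
    name: str
    standardize: bool = True


@dataclass(frozen=True)
class Interaction:
    terms: tuple

    def __init__(self, *terms):
        object.__setattr__(self, "terms", tuple(terms))


@dataclass(frozen=True)
class Smooth:
    """Penalized thin-plate spline smooth of a continuous covariate.

    With ``by`` set to a tuple of factor names, a shared reference smooth
    plus one sum-to-zero difference smooth per cell of the factor
    combination is built (a smooth-by-factor interaction)."""

    name: str
    k: int = 10
    by: tuple | None = None


@dataclass(frozen=True)
class Monotonic:
    name: str
    n_levels: int | None = None  # max ordinal level D; inferred if None


@dataclass(frozen=True)
class RandomEffects:
    """Correlated group-level intercept and slopes for one grouping factor."""

    group: str
    slopes: tuple = ()


@dataclass(frozen=True)
class PriorSet:
    fixed_scale: float = 2.5
    intercept_scale: float = 2.5
    sd_scale: float = 1.0  # half-normal on group SDs and smooth scales
    offdiag_scale: float = 0.5  # Cholesky off-diagonal entries
    simplex_concentration: float = 1.0  # Dirichlet concentration
    sigma_scale: float = 1.0  # half-normal on residual SD
    shape_log_loc: float = 0.0  # normal prior on log Gamma shape
    shape_log_scale: float = 1.5

    def __post_init__(self):
        for f in (
            "fixed_scale",
            "intercept_scale",
            "sd_scale",
            "offdiag_scale",
            "simplex_concentration",
            "sigma_scale",
            "shape_log_scale",
        ):
            if getattr(self, f) <= 0:
                raise ValueError(f"prior scale {f} must be positive")


@dataclass
class ModelSpec:
    family: str
    response: str
    terms: list = field(default_factory=list)
    random: list = field(default_factory=list)
    trials: object = None  # int or column name (binomial)
    se_col: str | None = None  # known per-observation SE (gaussian)
    estimate_sigma: bool = True  # residual SD (gaussian)
    priors: PriorSet = field(default_factory=PriorSet)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if self.family == "binomial_logit" and self.trials is None:
            raise ValueError("binomial family requires `trials`")


# ---------------------------------------------------------------------------
# fixed-effect column pieces (evaluable on new data)


class _Piece:
    names: list

    def eval(self, df: pd.DataFrame) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _InterceptPiece(_Piece):
    names = ["Intercept"]

    def eval(self, df):
        return np.ones((len(df), 1))


class _FactorPiece(_Piece):
    def __init__(self, name, levels, coding):
        self.name = name
        self.levels = list(levels)
        self.coding = coding
        k = len(self.levels)
        if coding == "orthonormal":
            self.C = orthonormal_contrasts(k)
            self.names = [f"{name}.c{j + 1}" for j in range(k - 1)]
        elif coding == "treatment":
            self.C = np.vstack([np.zeros(k - 1), np.eye(k - 1)])
            self.names = [f"{name}[{lev}]" for lev in self.levels[1:]]
        else:
            raise ValueError(f"unknown coding {coding!r}")

    def codes(self, df):
        idx = pd.Categorical(df[self.name], categories=self.levels).codes
        if np.any(idx < 0):
            bad = sorted(set(df[self.name]) - set(self.levels))
            raise ValueError(f"factor {self.name!r}: unseen level(s) {bad}")
        return np.asarray(idx)

    def eval(self, df):
        return self.C[self.codes(df)]


class _ContinuousPiece(_Piece):
    def __init__(self, name, center, scale):
        self.name = name
        self.center = center
        self.scale = scale
        self.names = [name]

    def eval(self, df):
        x = np.asarray(df[self.name], dtype=float)
        return ((x - self.center) / self.scale)[:, None]


class _InteractionPiece(_Piece):
    def __init__(self, pieces):
        self.pieces = pieces
        self.names = []
        idx = [range(len(p.names)) for p in pieces]
        from itertools import product

        self._combos = list(product(*idx))
        for combo in self._combos:
            self.names.append(
                ":".join(p.names[i] for p, i in zip(pieces, combo))
            )

    def eval(self, df):
        mats = [p.eval(df) for p in self.pieces]
        cols = []
        for combo in self._combos:
            col = np.ones(len(df))
            for mat, i in zip(mats, combo):
                col = col * mat[:, i]
            cols.append(col)
        return np.column_stack(cols)


class _SmoothLinearPiece(_Piece):
    """Unpenalized linear (null-space) part of a smooth, optionally times a
    by-cell indicator."""

    def __init__(self, block):
        self.block = block
        self.names = [f"s({block.label}).lin"]

    def eval(self, df):
        return self.block.linear_column(df)[:, None]


# ---------------------------------------------------------------------------
# smooth / monotonic / random blocks


@dataclass
class SmoothBlock:
    label: str
    var: str
    ev: object  # TprsEvaluator
    reparam: np.ndarray  # (k-2, m) maps raw nonlinear cols -> identity-penalty cols
    lin_scale: float
    pen_scale: float
    m: int
    by_info: tuple | None = None  # (factor_pieces, cell_codes_tuple)
    B: np.ndarray | None = None  # (n, m) penalized design at the observed data

    def _indicator(self, df):
        if self.by_info is None:
            return np.ones(len(df))
        pieces, cell = self.by_info
        ind = np.ones(len(df))
        for p, c in zip(pieces, cell):
            ind = ind * (p.codes(df) == c)
        return ind

    def linear_column(self, df):
        raw = self.ev(np.asarray(df[self.var], dtype=float))
        return raw[:, 0] / self.lin_scale * self._indicator(df)

    def penalized(self, df):
        raw = self.ev(np.asarray(df[self.var], dtype=float))
        return (raw[:, 1:] @ self.reparam) / self.pen_scale * self._indicator(df)[:, None]


@dataclass
class MonoBlock:
    name: str
    D: int

    def levels(self, df):
        lev = np.asarray(df[self.name], dtype=int)
        if np.any(lev < 0) or np.any(lev > self.D):
            raise ValueError(
                f"monotonic term {self.name!r}: levels outside 0..{self.D}"
            )
        return lev


@dataclass
class RandomBlock:
    group: str
    levels: list
    codes: np.ndarray  # (n,)
    W: np.ndarray  # (n, q): intercept + slope columns
    w_names: list
    q: int
    J: int


# ---------------------------------------------------------------------------
# built model


@dataclass
class BuiltModel:
    spec: ModelSpec
    data: pd.DataFrame
    y: np.ndarray
    trials: np.ndarray | None
    se: np.ndarray | None
    pieces: list
    X: np.ndarray
    colnames: list
    prior_loc: np.ndarray
    prior_scale: np.ndarray
    smooths: list
    monos: list
    randoms: list
    slices: dict
    names: list  # one name per scalar parameter
    n_params: int

    # -- parameter bookkeeping ------------------------------------------------

    def beta(self, theta):
        return theta[..., self.slices["beta"]]

    def param_index(self, name: str) -> int:
        return self.names.index(name)

    # -- linear predictor -----------------------------------------------------

    def eta(self, theta, design=None, include_random=True):
        """Linear predictor for a single parameter vector at the observed
        data (or a transformed design)."""
        th = np.asarray(theta, dtype=float)
        observed = design is None
        if observed:
            design = {
                "X": self.X,
                "smooth_B": [s.B for s in self.smooths],
                "mono_levels": [m.levels(self.data) for m in self.monos],
            }
        eta = design["X"] @ th[self.slices["beta"]]
        for i, s in enumerate(self.smooths):
            tau = np.exp(th[self.slices[("smooth", i, "log_tau")]][0])
            z = th[self.slices[("smooth", i, "z")]]
            eta = eta + tau * (design["smooth_B"][i] @ z)
        for i, m in enumerate(self.monos):
            beta_m = th[self.slices[("mono", i, "beta")]][0]
            zeta = self._mono_simplex(th, i)
            cum = np.concatenate([[0.0], np.cumsum(zeta)])
            eta = eta + beta_m * cum[design["mono_levels"][i]]
        if include_random and observed:
            # group effects only exist for the observed grouping; population
            # level predictions on new designs set them to zero
            for i, rb in enumerate(self.randoms):
                b = self._rand_b(th, i)
                eta = eta + np.sum(rb.W * b[rb.codes], axis=1)
        return eta

    def _mono_simplex(self, th, i):
        u = np.atleast_1d(th[self.slices[("mono", i, "u")]])
        w = np.concatenate([u, [0.0]])
        w = w - w.max()
        e = np.exp(w)
        return e / e.sum()

    def _rand_A(self, th, i):
        rb = self.randoms[i]
        q = rb.q
        ld = th[self.slices[("rand", i, "log_d")]]
        off = th[self.slices[("rand", i, "off")]]
        A = np.zeros((q, q))
        A[np.diag_indices(q)] = np.exp(ld)
        if q > 1:
            A[np.tril_indices(q, -1)] = off
        return A

    def _rand_b(self, th, i):
        rb = self.randoms[i]
        z = th[self.slices[("rand", i, "z")]].reshape(rb.J, rb.q)
        return z @ self._rand_A(th, i).T

    # -- transform new data ---------------------------------------------------

    def required_columns(self):
        cols = set()
        for p in self.pieces:
            for attr in ("name",):
                if hasattr(p, attr):
                    cols.add(getattr(p, attr))
            if isinstance(p, _InteractionPiece):
                for sub in p.pieces:
                    if hasattr(sub, "name"):
                        cols.add(sub.name)
            if isinstance(p, _SmoothLinearPiece):
                cols.add(p.block.var)
                if p.block.by_info:
                    for fp in p.block.by_info[0]:
                        cols.add(fp.name)
        for s in self.smooths:
            cols.add(s.var)
            if s.by_info:
                for fp in s.by_info[0]:
                    cols.add(fp.name)
        for m in self.monos:
            cols.add(m.name)
        cols.discard(None)
        return sorted(c for c in cols if isinstance(c, str))

    def factor_levels(self) -> dict:
        """Levels of every factor used anywhere in the design."""
        out = {}

        def walk(piece):
            if isinstance(piece, _FactorPiece):
                out[piece.name] = piece.levels
            elif isinstance(piece, _InteractionPiece):
                for sub in piece.pieces:
                    walk(sub)
            elif isinstance(piece, _SmoothLinearPiece) and piece.block.by_info:
                for fp in piece.block.by_info[0]:
                    walk(fp)

        for p in self.pieces:
            walk(p)
        for s in self.smooths:
            if s.by_info:
                for fp in s.by_info[0]:
                    out[fp.name] = fp.levels
        return out

    def complete_grid(self, grid: pd.DataFrame) -> pd.DataFrame:
        """Fill covariates missing from a prediction grid with reference
        values (continuous: data mean; factor: first level; ordinal: 0)."""
        grid = grid.copy()
        factors = self.factor_levels()
        for c in self.required_columns():
            if c in grid.columns:
                continue
            if c in factors:
                grid[c] = factors[c][0]
            elif any(m.name == c for m in self.monos):
                grid[c] = 0
            else:
                grid[c] = float(self.data[c].mean())
        return grid

    def design_at(self, grid: pd.DataFrame) -> dict:
        grid = self.complete_grid(grid)
        X = np.column_stack([p.eval(grid) for p in self.pieces]) if self.pieces else np.zeros((len(grid), 0))
        return {
            "X": X,
            "smooth_B": [s.penalized(grid) for s in self.smooths],
            "mono_levels": [m.levels(grid) for m in self.monos],
        }

    # -- response-scale helpers ----------------------------------------------

    def inverse_link(self, eta):
        if self.spec.family == "binomial_logit":
            return expit(eta)
        if self.spec.family == "gamma_log":
            return np.exp(eta)
        return eta

    def default_trials(self):
        if self.trials is None:
            return None
        return float(np.round(np.mean(self.trials)))


# ---------------------------------------------------------------------------
# building


def _make_piece(term, data, factor_cache):
    if isinstance(term, Factor):
        if term.name not in factor_cache:
            levels = sorted(pd.unique(data[term.name]))
            factor_cache[term.name] = levels
        return _FactorPiece(term.name, factor_cache[term.name], term.coding)
    if isinstance(term, Continuous):
        x = np.asarray(data[term.name], dtype=float)
        if term.standardize:
            center, scale = float(np.mean(x)), float(np.std(x))
            if scale == 0:
                raise ValueError(f"continuous term {term.name!r} is constant")
        else:
            center, scale = 0.0, 1.0
        return _ContinuousPiece(term.name, center, scale)
    if isinstance(term, Interaction):
        return _InteractionPiece(
            [_make_piece(t, data, factor_cache) for t in term.terms]
        )
    raise TypeError(f"cannot build design piece from {term!r}")


def _build_smooth_blocks(term: Smooth, data, factor_cache):
    """One reference smooth, plus per-cell difference smooths if `by` is
    given.  Difference smooths share the reference basis construction but
    are multiplied by the cell indicator; identifiability across the
    reference and deviation blocks is soft (shrinkage priors), matching a
    difference-smooth decomposition."""
    x = np.asarray(data[term.name], dtype=float)
    basis, penalty, ev = tprs_basis(x, k=term.k)
    S = penalty[1:, 1:]
    lam, V = np.linalg.eigh(S)
    keep = lam > max(lam.max(), 1.0) * 1e-10
    R = V[:, keep] / np.sqrt(lam[keep])
    raw_pen = basis[:, 1:] @ R
    pen_scale = float(np.sqrt(np.mean(raw_pen**2)))
    lin_scale = float(np.std(basis[:, 0]))
    blocks = []

    def mk(label, by_info):
        blk = SmoothBlock(
            label=label,
            var=term.name,
            ev=ev,
            reparam=R,
            lin_scale=lin_scale,
            pen_scale=pen_scale,
            m=int(keep.sum()),
            by_info=by_info,
        )
        blk.B = blk.penalized(data)
        return blk

    blocks.append(mk(f"{term.name}", None))
    if term.by is not None:
        by_names = term.by if isinstance(term.by, (tuple, list)) else (term.by,)
        pieces = []
        for nm in by_names:
            pieces.append(_make_piece(Factor(nm), data, factor_cache))
        from itertools import product

        level_ids = [range(len(p.levels)) for p in pieces]
        for cell in product(*level_ids):
            label = f"{term.name}|" + ",".join(
                f"{p.name}={p.levels[c]}" for p, c in zip(pieces, cell)
            )
            blocks.append(mk(label, (pieces, tuple(cell))))
    return blocks


def build_model(spec: ModelSpec, data: pd.DataFrame) -> BuiltModel:
    data = data.reset_index(drop=True)
    y = np.asarray(data[spec.response], dtype=float)
    trials = None
    if spec.family == "binomial_logit":
        if isinstance(spec.trials, str):
            trials = np.asarray(data[spec.trials], dtype=float)
        else:
            trials = np.full(len(data), float(spec.trials))
        if np.any(y < 0) or np.any(y > trials):
            raise ValueError("binomial response must satisfy 0 <= y <= trials")
    se = None
    if spec.se_col is not None:
        se = np.asarray(data[spec.se_col], dtype=float)
        if np.any(se < 0):
            raise ValueError("known SEs must be nonnegative")
    if spec.family == "gaussian_identity" and not spec.estimate_sigma and se is None:
        raise ValueError("gaussian model needs estimate_sigma=True or a known SE column")
    if spec.family == "gamma_log" and np.any(y <= 0):
        raise ValueError("gamma response must be strictly positive")

    factor_cache = {}
    pieces = [_InterceptPiece()]
    smooths, monos = [], []
    for term in spec.terms:
        if isinstance(term, Smooth):
            blocks = _build_smooth_blocks(term, data, factor_cache)
            for blk in blocks:
                smooths.append(blk)
                pieces.append(_SmoothLinearPiece(blk))
        elif isinstance(term, Monotonic):
            lev = np.asarray(data[term.name], dtype=int)
            if np.any(lev < 0):
                raise ValueError(f"ordinal term {term.name!r} has negative levels")
            D = term.n_levels if term.n_levels is not None else int(lev.max())
            if D < 1:
                raise ValueError(f"ordinal term {term.name!r} needs at least 2 levels")
            monos.append(MonoBlock(name=term.name, D=D))
        else:
            pieces.append(_make_piece(term, data, factor_cache))

    X = np.column_stack([p.eval(data) for p in pieces])
    colnames = [n for p in pieces for n in p.names]

    # data-derived intercept prior location on the link scale
    if spec.family == "binomial_logit":
        pbar = np.clip(np.mean(y / trials), 1e-3, 1 - 1e-3)
        icpt_loc = float(np.log(pbar / (1 - pbar)))
    elif spec.family == "gamma_log":
        icpt_loc = float(np.log(np.mean(y)))
    else:
        icpt_loc = float(np.mean(y))
    prior_loc = np.zeros(X.shape[1])
    prior_scale = np.full(X.shape[1], spec.priors.fixed_scale)
    prior_loc[0] = icpt_loc
    prior_scale[0] = spec.priors.intercept_scale

    randoms = []
    for rt in spec.random:
        levels = sorted(pd.unique(data[rt.group]))
        codes = pd.Categorical(data[rt.group], categories=levels).codes.astype(int)
        w_cols = [np.ones((len(data), 1))]
        w_names = ["Intercept"]
        for sl in rt.slopes:
            p = _make_piece(sl, data, factor_cache)
            w_cols.append(p.eval(data))
            w_names.extend(p.names)
        W = np.column_stack(w_cols)
        randoms.append(
            RandomBlock(
                group=rt.group,
                levels=levels,
                codes=codes,
                W=W,
                w_names=w_names,
                q=W.shape[1],
                J=len(levels),
            )
        )

    # parameter packing
    slices, names = {}, []
    pos = 0

    def add(key, size, namelist):
        nonlocal pos
        slices[key] = slice(pos, pos + size)
        names.extend(namelist)
        pos += size

    add("beta", X.shape[1], colnames)
    for i, s in enumerate(smooths):
        add(("smooth", i, "z"), s.m, [f"s({s.label}).z[{j}]" for j in range(s.m)])
        add(("smooth", i, "log_tau"), 1, [f"s({s.label}).log_tau"])
    for i, m in enumerate(monos):
        add(("mono", i, "beta"), 1, [f"mo({m.name}).beta"])
        add(("mono", i, "u"), m.D - 1, [f"mo({m.name}).u[{j}]" for j in range(m.D - 1)])
    for i, rb in enumerate(randoms):
        add(
            ("rand", i, "z"),
            rb.J * rb.q,
            [f"r({rb.group}).z[{j},{k}]" for j in range(rb.J) for k in range(rb.q)],
        )
        add(("rand", i, "log_d"), rb.q, [f"r({rb.group}).log_d[{k}]" for k in range(rb.q)])
        n_off = rb.q * (rb.q - 1) // 2
        add(("rand", i, "off"), n_off, [f"r({rb.group}).off[{k}]" for k in range(n_off)])
    if spec.family == "gaussian_identity" and spec.estimate_sigma:
        add("log_sigma", 1, ["log_sigma"])
    if spec.family == "gamma_log":
        add("log_shape", 1, ["log_shape"])

    return BuiltModel(
        spec=spec,
        data=data,
        y=y,
        trials=trials,
        se=se,
        pieces=pieces,
        X=X,
        colnames=colnames,
        prior_loc=prior_loc,
        prior_scale=prior_scale,
        smooths=smooths,
        monos=monos,
        randoms=randoms,
        slices=slices,
        names=names,
        n_params=pos,
    )


# ---------------------------------------------------------------------------
# log posterior and gradient


def _loglik_grad(model: BuiltModel, eta, theta):
    """Log likelihood, d ll / d eta, and gradients of family extras."""
    spec, y = model.spec, model.y
    extras = {}
    if spec.family == "binomial_logit":
        n = model.trials
        ll = np.sum(
            gammaln(n + 1)
            - gammaln(y + 1)
            - gammaln(n - y + 1)
            + y * eta
            - n * np.logaddexp(0.0, eta)
        )
        r = y - n * expit(eta)
    elif spec.family == "gaussian_identity":
        se2 = model.se**2 if model.se is not None else 0.0
        if spec.estimate_sigma:
            log_sigma = theta[model.slices["log_sigma"]][0]
            sigma2 = np.exp(2 * log_sigma)
        else:
            sigma2 = 0.0
        v = sigma2 + se2
        if np.isscalar(v):
            v = np.full_like(y, v)
        if np.any(v <= 0):
            raise ValueError("gaussian model: zero total variance for some row")
        resid = y - eta
        ll = np.sum(-0.5 * np.log(2 * np.pi * v) - resid**2 / (2 * v))
        r = resid / v
        if spec.estimate_sigma:
            extras["log_sigma"] = np.sum(-sigma2 / v + resid**2 * sigma2 / v**2)
    else:  # gamma_log
        log_shape = theta[model.slices["log_shape"]][0]
        alpha = np.exp(log_shape)
        mu = np.exp(eta)
        ll = np.sum(
            alpha * (log_shape - eta)
            - gammaln(alpha)
            + (alpha - 1) * np.log(y)
            - alpha * y / mu
        )
        r = alpha * (y / mu - 1.0)
        extras["log_shape"] = alpha * np.sum(
            log_shape + 1.0 - eta - psi(alpha) + np.log(y) - y / mu
        )
    return ll, r, extras


def _logp_grad(model: BuiltModel, theta: np.ndarray):
    """Joint log posterior and gradient.  Returns (lp, grad); lp is -inf
    (with zero grad) for numerically invalid states."""
    pr = model.spec.priors
    th = np.asarray(theta, dtype=float)
    grad = np.zeros_like(th)

    # assemble eta
    beta = th[model.slices["beta"]]
    eta = model.X @ beta
    smooth_parts = []
    for i, s in enumerate(model.smooths):
        log_tau = th[model.slices[("smooth", i, "log_tau")]][0]
        tau = np.exp(log_tau)
        z = th[model.slices[("smooth", i, "z")]]
        Bz = s.B @ z
        eta = eta + tau * Bz
        smooth_parts.append((tau, z, Bz))
    mono_parts = []
    for i, m in enumerate(model.monos):
        beta_m = th[model.slices[("mono", i, "beta")]][0]
        u = th[model.slices[("mono", i, "u")]]
        w = np.concatenate([u, [0.0]])
        w = w - w.max()
        e = np.exp(w)
        zeta = e / e.sum()
        cum = np.concatenate([[0.0], np.cumsum(zeta)])
        lev = m.levels(model.data)
        s_obs = cum[lev]
        eta = eta + beta_m * s_obs
        mono_parts.append((beta_m, zeta, lev, s_obs))
    rand_parts = []
    for i, rb in enumerate(model.randoms):
        z = th[model.slices[("rand", i, "z")]].reshape(rb.J, rb.q)
        A = model._rand_A(th, i)
        b = z @ A.T
        eta = eta + np.sum(rb.W * b[rb.codes], axis=1)
        rand_parts.append((z, A))

    try:
        ll, r, extras = _loglik_grad(model, eta, th)
    except (FloatingPointError, ValueError):
        return -np.inf, grad
    if not np.isfinite(ll):
        return -np.inf, grad

    lp = ll
    # fixed effects
    grad[model.slices["beta"]] = model.X.T @ r - (beta - model.prior_loc) / model.prior_scale**2
    lp += np.sum(-0.5 * ((beta - model.prior_loc) / model.prior_scale) ** 2)

    for i, s in enumerate(model.smooths):
        tau, z, Bz = smooth_parts[i]
        Btr = s.B.T @ r
        grad[model.slices[("smooth", i, "z")]] = tau * Btr - z
        lp += -0.5 * np.sum(z**2)
        # half-normal(sd_scale) on tau, log parameterization (Jacobian +log tau)
        grad[model.slices[("smooth", i, "log_tau")]] = (
            tau * (Bz @ r) - tau**2 / pr.sd_scale**2 + 1.0
        )
        lp += -0.5 * tau**2 / pr.sd_scale**2 + np.log(tau)

    for i, m in enumerate(model.monos):
        beta_m, zeta, lev, s_obs = mono_parts[i]
        grad[model.slices[("mono", i, "beta")]] = (
            r @ s_obs - beta_m / pr.fixed_scale**2
        )
        lp += -0.5 * (beta_m / pr.fixed_scale) ** 2
        # d ll / d zeta_k = beta_m * sum_{i: lev_i >= k} r_i
        bc = np.bincount(lev, weights=r, minlength=m.D + 1)
        tails = np.cumsum(bc[::-1])[::-1]  # tails[k] = sum over lev >= k
        g_zeta = beta_m * tails[1:]  # k = 1..D
        inner = g_zeta @ zeta
        g_u_full = zeta * (g_zeta - inner)
        conc = pr.simplex_concentration
        lp += conc * np.sum(np.log(zeta))
        g_u_full = g_u_full + conc * (1.0 - m.D * zeta)
        grad[model.slices[("mono", i, "u")]] = g_u_full[:-1]

    for i, rb in enumerate(model.randoms):
        z, A = rand_parts[i]
        G = np.zeros((rb.J, rb.q))
        np.add.at(G, rb.codes, rb.W * r[:, None])
        grad[model.slices[("rand", i, "z")]] = (G @ A - z).ravel()
        lp += -0.5 * np.sum(z**2)
        gA = G.T @ z
        d = np.diag(A)
        grad[model.slices[("rand", i, "log_d")]] = (
            np.diag(gA) * d - d**2 / pr.sd_scale**2 + 1.0
        )
        lp += np.sum(-0.5 * d**2 / pr.sd_scale**2 + np.log(d))
        if rb.q > 1:
            off = A[np.tril_indices(rb.q, -1)]
            g_off = gA[np.tril_indices(rb.q, -1)] - off / pr.offdiag_scale**2
            grad[model.slices[("rand", i, "off")]] = g_off
            lp += np.sum(-0.5 * (off / pr.offdiag_scale) ** 2)

    if "log_sigma" in extras:
        log_sigma = th[model.slices["log_sigma"]][0]
        sigma = np.exp(log_sigma)
        grad[model.slices["log_sigma"]] = (
            extras["log_sigma"] - sigma**2 / pr.sigma_scale**2 + 1.0
        )
        lp += -0.5 * sigma**2 / pr.sigma_scale**2 + log_sigma
    if "log_shape" in extras:
        log_shape = th[model.slices["log_shape"]][0]
        grad[model.slices["log_shape"]] = extras["log_shape"] - (
            log_shape - pr.shape_log_loc
        ) / pr.shape_log_scale**2
        lp += -0.5 * ((log_shape - pr.shape_log_loc) / pr.shape_log_scale) ** 2

    if not np.isfinite(lp):
        return -np.inf, np.zeros_like(grad)
    return lp, grad


def log_posterior(spec_or_model, data=None, params=None) -> float:
    """Joint log posterior (likelihood + priors + group-effect densities).

    Accepts either a ``BuiltModel`` or ``(ModelSpec, DataFrame)``; ``params``
    is the packed parameter vector.  Raises on non-finite results.
    """
    if isinstance(spec_or_model, BuiltModel):
        model = spec_or_model
    else:
        model = build_model(spec_or_model, data)
    th = np.asarray(params, dtype=float)
    if th.shape != (model.n_params,):
        raise ValueError(
            f"expected parameter vector of length {model.n_params}, got {th.shape}"
        )
    lp, _ = _logp_grad(model, th)
    if not np.isfinite(lp):
        eta = model.eta(th)
        if not np.all(np.isfinite(eta)):
            raise ValueError("non-finite linear predictor (check coefficients)")
        raise ValueError("non-finite log posterior (likelihood term)")
    return float(lp)
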