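"""Design-matrix primitives: orthonormal contrasts, low-rank thin-plate
regression spline bases, and monotonic (cumulative-simplex) encodings."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["orthonormal_contrasts", "tprs_basis", "monotonic_encoding", "TprsEvaluator"]


def orthonormal_contrasts(k: int) -> np.ndarray:
    """Orthonormal contrast coding for a k-level factor.

    Returns a k x (k-1) matrix whose columns are mutually orthonormal and
    orthogonal to the constant vector, so all pairwise level differences
    get equal marginal priors.  Deterministic (orthonormalized reverse
    Helmert): column j has j entries 1/sqrt(j(j+1)), then -j/sqrt(j(j+1)).
    """
    if k < 2:
        raise ValueError(f"need at least 2 factor levels, got {k}")
    C = np.zeros((k, k - 1))
    for j in range(1, k):
        norm = np.sqrt(j * (j + 1))
        C[:j, j - 1] = 1.0 / norm
        C[j, j - 1] = -j / norm
    return C


def _radial(r: np.ndarray) -> np.ndarray:
    """Thin-plate spline radial basis for d=1, m=2 penalty: |r|^3 (the
    positive constant of the Green's function is absorbed by the
    smoothing parameter)."""
    return np.abs(r) ** 3


@dataclass
class TprsEvaluator:
    """Frozen construction info so a fitted spline basis can be evaluated
    at new covariate values."""

    knots: np.ndarray  # (k,)
    null_proj: np.ndarray  # (k, k-2) null-space projection Q2
    col_means: np.ndarray  # (k-1,) centering offsets (linear col first)
    x_mean: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        E = _radial(x[:, None] - self.knots[None, :])
        nonlin = E @ self.null_proj
        lin = x - self.x_mean
        B = np.column_stack([lin, nonlin])
        return B - self.col_means


def tprs_basis(x: np.ndarray, k: int = 10):
    """Low-rank thin-plate regression spline basis with sum-to-zero
    constraint.

    The full thin-plate spline f(x) = a0 + a1 x + sum_j d_j |x - x_j|^3
    with the orthogonality constraint T' d = 0 (T = [1, x] at the knots) is
    restricted to ``k`` quantile knots.  The constraint is absorbed by
    projecting onto the null space of T', and every column is centered so
    the smooth sums to zero over the data (identifiability next to an
    intercept).  The unpenalized linear trend is kept as the first column;
    the penalty is the radial-basis energy, zero-padded for that column, so
    its null space contains the linear trend.

    Returns ``(basis, penalty, evaluator)``: basis is n x (k-1), penalty is
    (k-1) x (k-1) positive semidefinite, and ``evaluator`` reproduces the
    basis at new covariate values.
    """
    x = np.asarray(x, dtype=float)
    if k < 3:
        raise ValueError(f"basis dimension k must be >= 3, got {k}")
    ux = np.unique(x)
    if len(ux) < k:
        raise ValueError(
            f"need at least k={k} distinct covariate values, got {len(ux)}"
        )
    if np.ptp(ux) == 0:
        raise ValueError("degenerate covariate: all values equal")
    # quantile knots over the observed support, endpoints included
    knots = np.quantile(ux, np.linspace(0, 1, k))
    knots = np.unique(knots)
    if len(knots) < k:  # heavy ties; spread over unique values instead
        knots = ux[np.linspace(0, len(ux) - 1, k).round().astype(int)]
    E_kk = _radial(knots[:, None] - knots[None, :])
    T = np.column_stack([np.ones_like(knots), knots])
    # Q2 spans the null space of T' (k x (k-2))
    Q, _ = np.linalg.qr(T, mode="complete")
    Q2 = Q[:, 2:]
    S_nl = Q2.T @ E_kk @ Q2
    S_nl = 0.5 * (S_nl + S_nl.T)
    x_mean = float(np.mean(x))
    E_nk = _radial(x[:, None] - knots[None, :])
    raw = np.column_stack([x - x_mean, E_nk @ Q2])
    col_means = raw.mean(axis=0)
    basis = raw - col_means
    penalty = np.zeros((k - 1, k - 1))
    penalty[1:, 1:] = S_nl
    ev = TprsEvaluator(knots=knots, null_proj=Q2, col_means=col_means, x_mean=x_mean)
    return basis, penalty, ev


def monotonic_encoding(
    levels: np.ndarray, zeta: np.ndarray, beta: float
) -> np.ndarray:
    """Monotonic ordinal effect: effect(x) = beta * sum_{i<=x} zeta_i.

    ``levels`` are integers in 0..D with D = len(zeta); zeta is a simplex
    (nonnegative, sums to 1), so effect(0) = 0, effect(D) = beta, and the
    effect is monotone in the level for fixed beta.
    """
    zeta = np.asarray(zeta, dtype=float)
    if np.any(zeta < 0):
        raise ValueError("simplex weights must be nonnegative")
    if abs(zeta.sum() - 1.0) > 1e-8:
        raise ValueError(f"simplex weights must sum to 1, got {zeta.sum():.6f}")
    levels = np.asarray(levels, dtype=int)
    D = len(zeta)
    if np.any(levels < 0) or np.any(levels > D):
        raise ValueError(f"ordinal levels must lie in 0..{D}")
    cum = np.concatenate([[0.0], np.cumsum(zeta)])
    return beta * cum[levels]
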