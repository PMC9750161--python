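"""Samejima's graded response model fitted by marginal maximum likelihood.

The GRM relates ordered categories 0..K-1 of item j to latent factors theta
through cumulative logits

    P*(y_j >= t | theta) = logistic(a_j' theta - b_jt),   t = 1..K-1,

with category probabilities given by adjacent differences.  Estimation is an
EM algorithm: the E-step computes posterior weights of each response pattern
over a Gauss-Hermite grid (tensor grid for two factors); the M-step maximizes
each item's expected complete-data log-likelihood by quasi-Newton steps in a
monotone parameterization of the category bounds.  For k >= 2 factors the
exploratory model is identified by the echelon pattern (upper-triangle slopes
fixed at zero).

The logit metric approximates the normal-ogive/factor-analytic metric through
the scaling constant D = 1.702; `irt_to_fa` / `fa_to_irt` convert between the
two parameterizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit, logsumexp
from scipy.stats import chi2, norm
from sklearn.base import BaseEstimator

__all__ = [
    "GRMParams",
    "grm_category_probs",
    "grm_fit_em",
    "grm_lrt",
    "count_parameters",
    "irt_to_fa",
    "fa_to_irt",
    "GradedResponseModel",
]

D_SCALE = 1.702


@dataclass
class GRMParams:
    """Estimated GRM parameters in the logit metric."""

    slopes: np.ndarray  # p x k
    bounds: list[np.ndarray]  # per item, length K_j - 1, increasing
    k: int
    n_categories: list[int]
    loglik: float
    converged: bool = True
    n_iter: int = 0
    category_maps: list[np.ndarray] | None = None  # recorded collapses
    loglik_history: list[float] | None = None


def grm_category_probs(slopes_j: np.ndarray, bounds_j: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Category probabilities for one item at latent points theta (Q x k).

    Returns a (K, Q) array; rows sum to one.
    """
    bounds_j = np.asarray(bounds_j, float)
    if np.any(np.diff(bounds_j) <= 0):
        raise ValueError("category bounds must be strictly increasing")
    theta = np.atleast_2d(np.asarray(theta, float))
    z = theta @ np.atleast_1d(slopes_j)  # Q
    Pstar = expit(z[None, :] - bounds_j[:, None])  # (K-1, Q)
    top = np.ones((1, Pstar.shape[1]))
    bot = np.zeros((1, Pstar.shape[1]))
    cum = np.vstack([top, Pstar, bot])
    return cum[:-1] - cum[1:]


def _quad_grid(k: int, n_points: int):
    x, w = np.polynomial.hermite.hermgauss(n_points)
    nodes1 = x * np.sqrt(2.0)
    w1 = w / np.sqrt(np.pi)
    if k == 1:
        return nodes1[:, None], w1
    grids = np.meshgrid(*([nodes1] * k), indexing="ij")
    nodes = np.column_stack([g.ravel() for g in grids])
    weights = np.ones(nodes.shape[0])
    for g in np.meshgrid(*([w1] * k), indexing="ij"):
        weights *= g.ravel()
    return nodes, weights


def _item_neg_loglik(par, theta, r, free_slope_idx, k):
    """Expected complete-data negative log-likelihood for one item.

    Parameter vector: free slopes, then (b1, log-gaps) for the bounds.
    """
    n_free = len(free_slope_idx)
    K = r.shape[0]
    a = np.zeros(k)
    a[free_slope_idx] = par[:n_free]
    braw = par[n_free:]
    gaps = np.exp(braw[1:])
    b = braw[0] + np.concatenate(([0.0], np.cumsum(gaps)))
    z = theta @ a  # Q
    Pstar = expit(z[None, :] - b[:, None])  # (K-1, Q)
    cum = np.vstack([np.ones_like(z)[None, :], Pstar, np.zeros_like(z)[None, :]])
    p = np.maximum(cum[:-1] - cum[1:], 1e-300)
    f = -float(np.sum(r * np.log(p)))

    s = Pstar * (1.0 - Pstar)  # (K-1, Q)
    ratio = r / p  # (K, Q)
    dz = s * (ratio[1:, :] - ratio[:-1, :])  # dL/dz_t per node
    grad_a = dz.sum(axis=0) @ theta  # k-vector via theta columns
    ga = grad_a[free_slope_idx]
    gb = -dz.sum(axis=1)  # dL/db_t
    g1 = gb.sum()
    ggaps = np.array([gb[u:].sum() * gaps[u - 1] for u in range(1, K - 1)])
    grad = -np.concatenate([ga, [g1], ggaps])
    return f, grad


def _bounds_to_par(b):
    b = np.asarray(b, float)
    gaps = np.diff(b)
    return np.concatenate([[b[0]], np.log(np.maximum(gaps, 1e-6))])


def _par_to_bounds(braw):
    return braw[0] + np.concatenate(([0.0], np.cumsum(np.exp(braw[1:]))))


def _collapse_categories(column: np.ndarray):
    values, recoded = np.unique(column, return_inverse=True)
    return recoded.astype(np.int64), values


def grm_fit_em(
    data: np.ndarray,
    k: int = 1,
    quad_points: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 200,
    init: tuple | None = None,
) -> GRMParams:
    """Fit the GRM by marginal ML (EM with Gauss-Hermite quadrature).

    ``init`` is an optional warm start ``(slopes, bounds)``; slopes with fewer
    columns than ``k`` are zero-padded (useful for nesting a converged
    (k-1)-factor solution inside the k-factor fit).
    """
    data = np.asarray(data)
    n, p = data.shape
    if quad_points is None:
        quad_points = 21 if k == 1 else 15
    recoded = np.empty_like(data)
    maps, n_cats = [], []
    for j in range(p):
        rec, vals = _collapse_categories(data[:, j])
        if len(vals) < 2:
            raise ValueError(f"item {j} is constant")
        recoded[:, j] = rec
        maps.append(vals)
        n_cats.append(len(vals))

    patterns, counts = np.unique(recoded, axis=0, return_counts=True)
    theta, wq = _quad_grid(k, quad_points)
    Q = theta.shape[0]

    # echelon identification: item j < k has slopes for factors > j fixed at 0
    free_idx = [np.arange(min(j + 1, k)) if j < k - 1 else np.arange(k) for j in range(p)]
    slopes = np.zeros((p, k))
    for j in range(p):
        slopes[j, free_idx[j]] = 1.0
    bounds = []
    for j in range(p):
        cum = np.cumsum(np.bincount(recoded[:, j], minlength=n_cats[j]))[:-1] / n
        b0 = D_SCALE * norm.ppf(cum)
        b0 = np.maximum.accumulate(b0 + 1e-6 * np.arange(len(b0)))
        bounds.append(b0)
    if init is not None:
        s0, b0s = init
        s0 = np.atleast_2d(np.asarray(s0, float))
        # warm start: copy provided columns, break symmetry in the new ones
        slopes[:, : s0.shape[1]] = s0
        for j in range(p):
            extra = free_idx[j][free_idx[j] >= s0.shape[1]]
            slopes[j, extra] = 0.3
            slopes[j, ~np.isin(np.arange(k), free_idx[j])] = 0.0
        bounds = [np.asarray(b, float).copy() for b in b0s]

    loglik_old = -np.inf
    loglik = -np.inf
    converged = False
    history: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        logL = np.zeros((len(patterns), Q))
        logP_items = []
        for j in range(p):
            pj = np.maximum(grm_category_probs(slopes[j], bounds[j], theta), 1e-300)
            logpj = np.log(pj)
            logP_items.append(logpj)
            logL += logpj[patterns[:, j], :]
        logL_w = logL + np.log(wq)[None, :]
        lse = logsumexp(logL_w, axis=1)
        loglik = float(np.sum(counts * lse))
        history.append(loglik)
        W = np.exp(logL_w - lse[:, None]) * counts[:, None]  # pattern x Q

        if loglik - loglik_old < tol and it > 1:
            converged = True
            break
        loglik_old = loglik

        # M-step, item by item
        for j in range(p):
            Kj = n_cats[j]
            r = np.zeros((Kj, Q))
            np.add.at(r, patterns[:, j], W)
            par0 = np.concatenate([slopes[j, free_idx[j]], _bounds_to_par(bounds[j])])
            res = optimize.minimize(
                _item_neg_loglik,
                par0,
                args=(theta, r, free_idx[j], k),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 60, "ftol": 1e-12},
            )
            nf = len(free_idx[j])
            slopes[j] = 0.0
            slopes[j, free_idx[j]] = res.x[:nf]
            bounds[j] = _par_to_bounds(res.x[nf:])

    n_par = int(sum(len(fi) for fi in free_idx) + sum(kc - 1 for kc in n_cats))
    params = GRMParams(
        slopes=slopes,
        bounds=bounds,
        k=k,
        n_categories=n_cats,
        loglik=loglik,
        converged=converged,
        n_iter=it,
        category_maps=maps,
        loglik_history=history,
    )
    params.n_parameters = n_par
    return params


def grm_marginal_loglik(data: np.ndarray, slopes: np.ndarray, bounds,
                        quad_points: int = 21) -> float:
    """Marginal log-likelihood of fixed GRM parameters (quadrature check)."""
    data = np.asarray(data)
    n, p = data.shape
    k = np.atleast_2d(slopes).shape[1]
    patterns, counts = np.unique(data, axis=0, return_counts=True)
    theta, wq = _quad_grid(k, quad_points)
    logL = np.zeros((len(patterns), theta.shape[0]))
    for j in range(p):
        pj = np.maximum(grm_category_probs(np.atleast_2d(slopes)[j], bounds[j], theta), 1e-300)
        logL += np.log(pj)[patterns[:, j], :]
    return float(np.sum(counts * logsumexp(logL + np.log(wq)[None, :], axis=1)))


def count_parameters(p: int, K: int, k: int, model: str = "GRM") -> int:
    """Free-parameter count for the exploratory GRM or nominal-categories model."""
    if p < 2 or K < 2 or k < 1:
        raise ValueError("need p >= 2, K >= 2, k >= 1")
    constr = k * (k - 1) // 2
    if model.upper() == "GRM":
        return p * k - constr + p * (K - 1)
    if model.upper() == "MNCM":
        return p * (k + (K - 2) + (K - 1)) - constr
    raise ValueError("model must be 'GRM' or 'MNCM'")


def grm_lrt(fit_k: GRMParams, fit_k1: GRMParams, neg_tol: float = 0.5):
    """Likelihood-ratio test between nested GRM fits (fit_k more restrictive).

    The larger model nests the smaller, so the true difference is >= 0; small
    negative values (within ``neg_tol``) reflect incomplete EM convergence of
    the larger fit and are clipped to zero.
    """
    dif = 2.0 * (fit_k1.loglik - fit_k.loglik)
    if dif < -neg_tol:
        raise ValueError(f"negative LR difference ({dif:.4g}); a fit did not converge")
    dif = max(dif, 0.0)
    df = fit_k1.n_parameters - fit_k.n_parameters
    p = float(chi2.sf(dif, df))
    return dif, df, p


def irt_to_fa(slopes: np.ndarray, bounds, D: float = D_SCALE):
    """Convert logit-metric IRT parameters to the FA parameterization.

    lambda_j = a*_j / sqrt(1 + ||a*_j||^2) with a* = a / D, and
    tau_jt = (b_jt / D) / sqrt(1 + ||a*_j||^2).
    """
    a_star = np.atleast_2d(np.asarray(slopes, float)) / D
    denom = np.sqrt(1.0 + np.sum(a_star**2, axis=1))
    lam = a_star / denom[:, None]
    taus = [np.asarray(b, float) / D / denom[j] for j, b in enumerate(bounds)]
    return lam, taus


def fa_to_irt(loadings: np.ndarray, thresholds, D: float = D_SCALE):
    """Inverse of :func:`irt_to_fa`."""
    lam = np.atleast_2d(np.asarray(loadings, float))
    comm = np.sum(lam**2, axis=1)
    if np.any(comm >= 1.0):
        raise ValueError("communalities must be < 1")
    denom = np.sqrt(1.0 - comm)
    a = D * lam / denom[:, None]
    b = [D * np.asarray(t, float) / denom[j] for j, t in enumerate(thresholds)]
    return a, b


class GradedResponseModel(BaseEstimator):
    """Samejima GRM estimator (sklearn-style) fitted by marginal ML EM.

    Attributes after ``fit``: ``slopes_``, ``bounds_``, ``loglik_``,
    ``n_parameters_``, ``loadings_``/``thresholds_`` (FA metric),
    ``converged_``, ``n_iter_``.
    """

    def __init__(self, n_factors: int = 1, quad_points: int | None = None,
                 tol: float = 1e-4, max_iter: int = 200):
        self.n_factors = n_factors
        self.quad_points = quad_points
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        params = grm_fit_em(
            np.asarray(X), self.n_factors, self.quad_points, self.tol, self.max_iter
        )
        self.params_ = params
        self.slopes_ = params.slopes
        self.bounds_ = params.bounds
        self.loglik_ = params.loglik
        self.n_parameters_ = params.n_parameters
        self.converged_ = params.converged
        self.n_iter_ = params.n_iter
        self.loadings_, self.thresholds_ = irt_to_fa(params.slopes, params.bounds)
        return self
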