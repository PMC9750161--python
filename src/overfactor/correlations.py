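"""Polychoric / tetrachoric correlations and the attenuation of Pearson correlation.

Polychoric estimation is the standard two-step procedure: thresholds from the
inverse-normal of marginal cumulative proportions, then pairwise maximum
likelihood for the latent correlation with thresholds held fixed.  The
asymptotic covariance of the estimates (needed by DWLS fitting and the
Satorra-Bentler corrections) comes from per-observation influence functions
with the threshold step profiled out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import ndtr
from scipy.stats import norm
from sklearn.base import BaseEstimator

from ._bvn import (
    bvn_cdf,
    rectangle_dprobs_drho,
    rectangle_dprobs_dtau,
    rectangle_probs,
)

__all__ = [
    "PolychoricResult",
    "AttenuationResult",
    "PolychoricCorrelation",
    "estimate_thresholds",
    "polychoric_pair",
    "polychoric_matrix",
    "acov_polychoric",
    "dichotomized_population_correlation",
    "ordinal_population_correlation",
    "nearest_pd_correlation",
]

_RHO_BOUND = 1.0 - 1e-6
_PROB_FLOOR = 1e-300


class DegenerateColumnError(ValueError):
    """A column is constant (or a pair's table has a zero margin)."""


@dataclass
class PolychoricResult:
    """Two-step polychoric estimates for a data matrix."""

    thresholds_hat: list[np.ndarray]
    rho_matrix: np.ndarray
    acov: np.ndarray | None
    n: int
    collapsed_categories: list[int]
    clamped_pairs: list[tuple[int, int]] = field(default_factory=list)
    smoothed: bool = False
    recoded: np.ndarray | None = None  # data recoded to observed categories


@dataclass(frozen=True)
class AttenuationResult:
    """Population Pearson correlation of a dichotomized bivariate-normal pair."""

    tau1: float
    tau2: float
    rho_star: float
    rho_y: float
    a: float


def estimate_thresholds(column: np.ndarray, K: int | None = None):
    """Inverse-normal thresholds from marginal cumulative proportions.

    Empty categories (boundary or interior) are collapsed; the returned
    recoded column uses consecutive codes 0..m-1 for the m observed
    categories.  Returns (thresholds, recoded_column, n_collapsed).
    """
    column = np.asarray(column)
    values, recoded = np.unique(column, return_inverse=True)
    m = len(values)
    if m < 2:
        raise DegenerateColumnError("column is constant; cannot estimate thresholds")
    n = len(column)
    counts = np.bincount(recoded, minlength=m)
    cum = np.cumsum(counts)[:-1] / n
    tau = norm.ppf(cum)
    n_collapsed = (int(K) - m) if K is not None else 0
    return tau, recoded.astype(np.int64), n_collapsed


def _pair_loglik(table: np.ndarray, a: np.ndarray, b: np.ndarray, rho: float) -> float:
    P = rectangle_probs(a, b, rho)
    return float(np.sum(table * np.log(np.maximum(P, _PROB_FLOOR))))


def polychoric_pair(
    x: np.ndarray,
    y: np.ndarray,
    thresholds: tuple[np.ndarray, np.ndarray] | None = None,
    xtol: float = 1e-6,
):
    """Two-step ML polychoric correlation for one pair of ordinal variables.

    Returns (rho_hat, info) where info carries thresholds, the contingency
    table, and a boundary-clamp flag.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if thresholds is None:
        a, xr, _ = estimate_thresholds(x)
        b, yr, _ = estimate_thresholds(y)
    else:
        a, b = (np.asarray(t, float) for t in thresholds)
        xr, yr = x.astype(np.int64), y.astype(np.int64)
    ma, mb = len(a) + 1, len(b) + 1
    table = np.bincount(xr * mb + yr, minlength=ma * mb).reshape(ma, mb).astype(float)
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise DegenerateColumnError("contingency table has a zero margin")

    res = optimize.minimize_scalar(
        lambda r: -_pair_loglik(table, a, b, r),
        bounds=(-_RHO_BOUND, _RHO_BOUND),
        method="bounded",
        options={"xatol": xtol},
    )
    rho = float(res.x)
    clamped = abs(rho) >= _RHO_BOUND - 1e-5
    if clamped:
        rho = float(np.sign(rho) * _RHO_BOUND)
    info = {"thresholds": (a, b), "table": table, "clamped": clamped, "loglik": -res.fun}
    return rho, info


def _pair_influence(rho, a, b, xr, yr):
    """Per-observation influence of one pairwise polychoric estimate.

    Profiles the estimated thresholds out via the information identity,
    g_i = I_rr^{-1} (s_rho,i - I_rtau' psi_tau,i), and also returns the
    model-implied (expected) variance of the influence, which is robust in
    sparse tables where rare high-information cells are unobserved.

    Returns (g, v_model).
    """
    # cells are floored well above the likelihood floor: near-boundary rho
    # estimates put fitted probabilities ~0 on observed cells, and the
    # resulting scores would numerically explode
    P = np.maximum(rectangle_probs(a, b, rho), 1e-6)
    dP = rectangle_dprobs_drho(a, b, rho)
    score_cell = dP / P
    I_rr = float(np.sum(dP * score_cell))
    if I_rr <= 0:
        raise DegenerateColumnError("singular pairwise information")
    g = score_cell[xr, yr]

    dP_da, dP_db = rectangle_dprobs_dtau(a, b, rho)
    ra, rb = len(a), len(b)
    phis = np.concatenate([norm.pdf(a), norm.pdf(b)])
    F_a = np.cumsum(P.sum(axis=1))[:ra]
    F_b = np.cumsum(P.sum(axis=0))[:rb]
    F = np.concatenate([F_a, F_b])
    # cross-information I_rho,tau and Cov(s_rho, psi_tau)
    d = np.empty(ra + rb)
    cov_s_psi = np.empty(ra + rb)
    for u in range(ra):
        d[u] = float(np.sum(score_cell * dP_da[u]))
        cov_s_psi[u] = float(dP[: u + 1, :].sum()) / phis[u]
    for v in range(rb):
        d[ra + v] = float(np.sum(score_cell * dP_db[v]))
        cov_s_psi[ra + v] = float(dP[:, : v + 1].sum()) / phis[ra + v]
    # Cov(psi_u, psi_v): (F_{u ^ v} - F_u F_v) / (phi_u phi_v)
    C = np.empty((ra + rb, ra + rb))
    for u in range(ra + rb):
        for v in range(u, ra + rb):
            if u < ra and v < ra:
                joint = F_a[min(u, v)]
            elif u >= ra and v >= ra:
                joint = F_b[min(u, v) - ra]
            else:
                joint = float(P[: u + 1, : v - ra + 1].sum())
            C[u, v] = C[v, u] = (joint - F[u] * F[v]) / (phis[u] * phis[v])
    v_model = (I_rr - 2.0 * d @ cov_s_psi + d @ C @ d) / I_rr**2

    cum_a = np.concatenate([F_a, [1.0]])
    cum_b = np.concatenate([F_b, [1.0]])
    for u in range(ra):
        g = g - d[u] * ((xr <= u) - cum_a[u]) / phis[u]
    for v in range(rb):
        g = g - d[ra + v] * ((yr <= v) - cum_b[v]) / phis[ra + v]
    g = g / I_rr
    return g - g.mean(), float(v_model)


def acov_polychoric(result: PolychoricResult, method: str = "hybrid") -> np.ndarray:
    """Asymptotic covariance (of sqrt(n)*(rho_hat - rho)) for the lower triangle.

    ``method='empirical'``: Gamma_hat = (1/n) sum_i g_i g_i' with g_i the
    stacked per-pair influences.  ``method='hybrid'`` (default) replaces the
    diagonal by the model-implied influence variances and keeps the empirical
    correlations between influences; in sparse tables with extreme thresholds
    the purely empirical variances are badly downward-biased because the rare
    cells that carry most of the information are unobserved.
    """
    data = result.recoded
    if data is None:
        raise ValueError("PolychoricResult must carry recoded data for acov")
    n, p = data.shape
    pairs = [(j, k) for j in range(1, p) for k in range(j)]
    G = np.empty((n, len(pairs)))
    v_model = np.empty(len(pairs))
    for idx, (j, k) in enumerate(pairs):
        G[:, idx], v_model[idx] = _pair_influence(
            result.rho_matrix[j, k],
            result.thresholds_hat[j],
            result.thresholds_hat[k],
            data[:, j],
            data[:, k],
        )
    gamma = G.T @ G / n
    if method == "hybrid":
        d_emp = np.sqrt(np.maximum(np.diag(gamma), 1e-12))
        corr = gamma / np.outer(d_emp, d_emp)
        np.fill_diagonal(corr, 1.0)
        d_mod = np.sqrt(np.maximum(v_model, 1e-12))
        gamma = corr * np.outer(d_mod, d_mod)
    elif method != "empirical":
        raise ValueError("method must be 'hybrid' or 'empirical'")
    result.acov = gamma
    return gamma


def nearest_pd_correlation(R: np.ndarray, eig_floor: float = 1e-6):
    """Eigenvalue-clipped nearest-PD smoothing, re-normalized to unit diagonal."""
    w, V = np.linalg.eigh(R)
    if w.min() > eig_floor:
        return R, False
    w = np.maximum(w, eig_floor)
    S = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    np.fill_diagonal(S, 1.0)
    return S, True


def polychoric_matrix(data: np.ndarray, compute_acov: bool = True) -> PolychoricResult:
    """Pairwise two-step polychoric correlation matrix with asymptotic covariance."""
    data = np.asarray(data)
    n, p = data.shape
    thresholds, recoded, collapsed = [], np.empty_like(data, dtype=np.int64), []
    for j in range(p):
        try:
            tau, rec, nc = estimate_thresholds(data[:, j])
        except DegenerateColumnError as e:
            raise DegenerateColumnError(f"column {j}: {e}") from None
        thresholds.append(tau)
        recoded[:, j] = rec
        collapsed.append(nc)

    R = np.eye(p)
    clamped_pairs = []
    for j in range(1, p):
        for k in range(j):
            try:
                rho, info = polychoric_pair(
                    recoded[:, j], recoded[:, k], thresholds=(thresholds[j], thresholds[k])
                )
            except DegenerateColumnError as e:
                raise DegenerateColumnError(f"pair ({j},{k}): {e}") from None
            R[j, k] = R[k, j] = rho
            if info["clamped"]:
                clamped_pairs.append((j, k))

    R, smoothed = nearest_pd_correlation(R)
    result = PolychoricResult(
        thresholds_hat=thresholds,
        rho_matrix=R,
        acov=None,
        n=n,
        collapsed_categories=collapsed,
        clamped_pairs=clamped_pairs,
        smoothed=smoothed,
        recoded=recoded,
    )
    if compute_acov:
        acov_polychoric(result)
    return result


class PolychoricCorrelation(BaseEstimator):
    """Two-step polychoric correlation estimator (sklearn-style).

    Attributes after ``fit``: ``rho_``, ``acov_``, ``thresholds_``,
    ``smoothed_``, ``collapsed_categories_``, ``n_``.
    """

    def __init__(self, compute_acov: bool = True):
        self.compute_acov = compute_acov

    def fit(self, X, y=None):
        X = np.asarray(X)
        result = polychoric_matrix(X, compute_acov=self.compute_acov)
        self.result_ = result
        self.rho_ = result.rho_matrix
        self.acov_ = result.acov
        self.thresholds_ = result.thresholds_hat
        self.smoothed_ = result.smoothed
        self.collapsed_categories_ = result.collapsed_categories
        self.n_ = result.n
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).rho_


def dichotomized_population_correlation(tau1: float, tau2: float, rho_star: float) -> AttenuationResult:
    """Population Pearson correlation of two dichotomized one-factor indicators.

    With p_j = 1 - Phi(tau_j) and P11 the upper-rectangle probability of the
    standard bivariate normal with correlation rho_star,
    rho_y = (P11 - p1 p2) / sqrt(p1 (1-p1) p2 (1-p2)).
    """
    if not -1.0 < rho_star < 1.0:
        raise ValueError("rho_star must lie in (-1, 1)")
    p1 = 1.0 - ndtr(tau1)
    p2 = 1.0 - ndtr(tau2)
    if min(p1, 1 - p1, p2, 1 - p2) < 1e-15:
        raise ValueError("threshold so extreme that a marginal probability underflows")
    P11 = 1.0 - ndtr(tau1) - ndtr(tau2) + float(bvn_cdf(tau1, tau2, rho_star))
    rho_y = (P11 - p1 * p2) / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    a = rho_y / rho_star if rho_star != 0.0 else np.nan
    return AttenuationResult(float(tau1), float(tau2), float(rho_star), float(rho_y), float(a))


def ordinal_population_correlation(tau1: np.ndarray, tau2: np.ndarray, rho_star: float) -> float:
    """Population Pearson correlation of two polytomized one-factor indicators.

    Generalizes the dichotomous attenuation result: with Y = #{thresholds
    below y*}, E[Y1 Y2] is a sum of upper-rectangle probabilities over all
    threshold pairs.
    """
    tau1 = np.asarray(tau1, float)
    tau2 = np.asarray(tau2, float)
    p1 = 1.0 - ndtr(tau1)
    p2 = 1.0 - ndtr(tau2)
    e1, e2 = p1.sum(), p2.sum()
    H, K = np.meshgrid(tau1, tau2, indexing="ij")
    upper = 1.0 - ndtr(H) - ndtr(K) + bvn_cdf(H, K, rho_star)
    e12 = float(upper.sum())
    # marginal variance of Y: E[Y^2] via within-item threshold pairs at rho=1
    def _var(tau, p):
        H1, H2 = np.meshgrid(tau, tau, indexing="ij")
        up = 1.0 - ndtr(np.maximum(H1, H2))
        return float(up.sum()) - p.sum() ** 2

    v1, v2 = _var(tau1, p1), _var(tau2, p2)
    return (e12 - e1 * e2) / np.sqrt(v1 * v2)
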