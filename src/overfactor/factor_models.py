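"""Exploratory factor models for ordinal-data dimensionality testing.

Implements maximum-likelihood exploratory factor analysis of a correlation or
covariance matrix via the uniqueness-profile (eigenvalue) algorithm,
diagonally weighted least squares (DWLS) on polychoric correlations, and the
Satorra-Bentler family of robust test statistics:

* mean-corrected ``T_M = T / c`` with ``c = tr(U Gamma) / df``,
* mean-and-variance corrected ``T_MV = T/a + b`` (scale-and-shift, matching
  the first two moments of chi-square), and
* the scaled chi-square difference ``dT_M`` for nested models.

The discrepancy function is F(S, Sigma) = log|Sigma| - log|S| +
trace(S Sigma^{-1}) - p, with X^2 = N * F by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .correlations import PolychoricResult, polychoric_matrix

__all__ = [
    "FAModelFit",
    "PopulationAnalysis",
    "efa_df",
    "ml_factor_fit",
    "dwls_fit",
    "mean_corrected_statistic",
    "mean_variance_corrected_statistic",
    "scaled_chisq_difference",
    "population_discrepancy",
    "MLFactorAnalysis",
    "DWLSFactorAnalysis",
]

_PSI_FLOOR = 1e-4


def efa_df(p: int, k: int) -> int:
    """Degrees of freedom of the exploratory k-factor model for p variables."""
    if k < 0:
        raise ValueError("k must be >= 0")
    df = ((p - k) ** 2 - (p + k)) / 2
    if df < 0:
        raise ValueError(f"k={k} factors not identified for p={p} variables (df={df:g} < 0)")
    return int(df)


@dataclass
class FAModelFit:
    """A fitted exploratory factor model and its test statistic."""

    k: int
    loadings: np.ndarray
    uniquenesses: np.ndarray
    F_min: float
    chisq: float
    df: int
    p_value: float
    n: int
    method: str
    converged: bool
    heywood: bool
    scaling: dict = field(default_factory=dict)
    # machinery for robust corrections (residual weights / Jacobian / Gamma)
    extras: dict = field(default_factory=dict, repr=False)


@dataclass(frozen=True)
class PopulationAnalysis:
    """Population misfit of the k-factor linear structure."""

    F0: float
    df: int
    rmsea: float
    delta: float | None = None


# ---------------------------------------------------------------------------
# ML factor analysis (uniqueness-profile algorithm)
# ---------------------------------------------------------------------------


def _profile_objective(log_psi, S, k):
    psi = np.exp(log_psi)
    isr = 1.0 / np.sqrt(psi)
    A = S * np.outer(isr, isr)
    w, V = np.linalg.eigh(A)  # ascending
    m = len(psi) - k
    theta = w[:m]
    vecs = V[:, :m]
    f = float(np.sum(theta - np.log(theta) - 1.0))
    grad = -np.sum((theta - 1.0) * vecs**2, axis=1)  # d f / d log psi
    return f, grad


def _ml_profile_fit(S: np.ndarray, k: int, max_iter: int = 500):
    p = S.shape[0]
    diag = np.diag(S)
    Sinv_d = np.diag(np.linalg.inv(S))
    psi0 = np.clip((1.0 - 0.5 * k / p) / Sinv_d, _PSI_FLOOR * diag, diag)
    lb = np.log(_PSI_FLOOR * diag)
    ub = np.log(diag)
    res = optimize.minimize(
        _profile_objective,
        np.log(psi0),
        args=(S, k),
        jac=True,
        method="L-BFGS-B",
        bounds=list(zip(lb, ub)),
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
    )
    psi = np.exp(res.x)
    isr = 1.0 / np.sqrt(psi)
    A = S * np.outer(isr, isr)
    w, V = np.linalg.eigh(A)
    order = np.argsort(w)[::-1]
    theta = w[order[:k]]
    vecs = V[:, order[:k]]
    lam = np.sqrt(psi)[:, None] * vecs * np.sqrt(np.maximum(theta - 1.0, 0.0))[None, :]
    heywood = bool(np.any(res.x <= lb + 1e-8))
    converged = bool(res.success or np.max(np.abs(res.jac)) < 1e-5)
    return lam, psi, float(res.fun), converged, heywood


def _chisq_multiplier(n: int, p: int, k: int, kind: str) -> float:
    if kind == "n":
        return float(n)
    if kind == "bartlett":
        return float(n - 1 - (2 * p + 5) / 6.0 - 2 * k / 3.0)
    raise ValueError("chisq multiplier must be 'n' or 'bartlett'")


def ml_factor_fit(
    R: np.ndarray,
    k: int,
    n: int,
    chisq_multiplier: str = "n",
    method_label: str = "ML-FA",
) -> FAModelFit:
    """Maximum-likelihood exploratory factor fit to a correlation/covariance matrix."""
    R = np.asarray(R, float)
    p = R.shape[0]
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("input matrix must be symmetric")
    if np.linalg.eigvalsh(R).min() <= 0:
        raise ValueError("input matrix is not positive definite; smooth it first")
    df = efa_df(p, k)
    if k == 0:
        lam = np.zeros((p, 0))
        psi = np.diag(R).copy()
        isr = 1.0 / np.sqrt(psi)
        A = R * np.outer(isr, isr)
        w = np.linalg.eigvalsh(A)
        F = float(np.sum(w - np.log(w) - 1.0))
        converged, heywood = True, False
    else:
        lam, psi, F, converged, heywood = _ml_profile_fit(R, k)
    mult = _chisq_multiplier(n, p, k, chisq_multiplier)
    chisq = mult * F
    p_value = float(chi2.sf(chisq, df)) if df > 0 else 1.0
    return FAModelFit(
        k=k,
        loadings=lam,
        uniquenesses=psi,
        F_min=F,
        chisq=chisq,
        df=df,
        p_value=p_value,
        n=n,
        method=method_label,
        converged=converged,
        heywood=heywood,
        extras={"sigma": R, "multiplier": chisq_multiplier},
    )


# ---------------------------------------------------------------------------
# DWLS (WLSMV) on polychoric correlations
# ---------------------------------------------------------------------------


def _pair_index(p: int):
    return [(j, k) for j in range(1, p) for k in range(j)]


def _dwls_objective(vec_lam, p, k, s, w):
    lam = vec_lam.reshape(p, k)
    C = lam @ lam.T
    pairs = _pair_index(p)
    sigma = np.array([C[j, m] for j, m in pairs])
    e = s - sigma
    M = np.zeros((p, p))
    for idx, (j, m) in enumerate(pairs):
        M[j, m] = M[m, j] = w[idx] * e[idx]
    f = float(np.sum(w * e * e))
    grad = (-2.0 * M @ lam).ravel()
    return f, grad


def _dwls_delta(lam: np.ndarray) -> np.ndarray:
    """Jacobian d sigma_l / d vec(Lambda) for the off-diagonal structure."""
    p, k = lam.shape
    pairs = _pair_index(p)
    D = np.zeros((len(pairs), p * k))
    for l, (j, m) in enumerate(pairs):
        for f in range(k):
            D[l, j * k + f] += lam[m, f]
            D[l, m * k + f] += lam[j, f]
    return D


def dwls_fit(poly: PolychoricResult, k: int, start: np.ndarray | None = None) -> FAModelFit:
    """Diagonally weighted least squares factor fit to a polychoric matrix.

    Minimizes (s - sigma(Lambda))' W^{-1} (s - sigma(Lambda)) with
    W = diag(Gamma_hat) over the lower-triangle correlation vector s;
    uniquenesses are implied by the unit-diagonal correlation structure.
    """
    R = poly.rho_matrix
    gamma = poly.acov
    if gamma is None:
        raise ValueError("PolychoricResult.acov is required for DWLS; run acov_polychoric")
    p = R.shape[0]
    n = poly.n
    df = efa_df(p, k)
    wdiag = np.diag(gamma)
    if np.any(wdiag <= 0):
        bad = int(np.argmin(wdiag))
        raise ValueError(f"zero/negative diagonal in Gamma_hat at element {bad}")
    w = 1.0 / wdiag
    pairs = _pair_index(p)
    s = np.array([R[j, m] for j, m in pairs])

    if start is None:
        start_fit = ml_factor_fit(R, k, n)
        lam0 = start_fit.loadings
    else:
        lam0 = start
    res = optimize.minimize(
        _dwls_objective,
        lam0.ravel(),
        args=(p, k, s, w),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    lam = res.x.reshape(p, k)
    comm = np.sum(lam**2, axis=1)
    psi = 1.0 - comm
    heywood = bool(np.any(psi < 0))
    F = float(res.fun)
    chisq = n * F
    p_value = float(chi2.sf(chisq, df)) if df > 0 else 1.0
    C = lam @ lam.T
    sigma = np.array([C[j, m] for j, m in pairs])
    fit = FAModelFit(
        k=k,
        loadings=lam,
        uniquenesses=psi,
        F_min=F,
        chisq=chisq,
        df=df,
        p_value=p_value,
        n=n,
        method="WLSMV",
        converged=bool(res.success),
        heywood=heywood,
        extras={
            "weight_diag": w,
            "delta": _dwls_delta(lam),
            "residuals": s - sigma,
            "gamma": gamma,
        },
    )
    return fit


# ---------------------------------------------------------------------------
# Satorra-Bentler corrections
# ---------------------------------------------------------------------------


def _ugamma(fit: FAModelFit, gamma_acov: np.ndarray | None = None) -> np.ndarray:
    """U Gamma with U the residual-projection weight matrix of the estimator."""
    gamma = gamma_acov if gamma_acov is not None else fit.extras.get("gamma")
    if gamma is None:
        raise ValueError("an asymptotic covariance matrix Gamma is required")
    if "weight_diag" in fit.extras:  # DWLS
        V = np.diag(fit.extras["weight_diag"])
    else:
        V = fit.extras["weight_full"]
    delta = fit.extras["delta"]
    VD = V @ delta
    middle = np.linalg.pinv(delta.T @ VD, rcond=1e-10)
    U = V - VD @ middle @ VD.T
    fit.extras["U"] = U
    return U @ gamma


def mean_corrected_statistic(fit: FAModelFit, gamma_acov: np.ndarray | None = None):
    """Satorra-Bentler mean-corrected statistic: T_M = T/c, c = tr(U Gamma)/df."""
    UG = _ugamma(fit, gamma_acov)
    c = float(np.trace(UG)) / fit.df
    if c <= 0:
        raise ValueError("non-positive scaling constant c; pathological Gamma")
    T_M = fit.chisq / c
    p = float(chi2.sf(T_M, fit.df))
    fit.scaling["c"] = c
    fit.scaling["T_M"] = T_M
    return T_M, c, p


def mean_variance_corrected_statistic(fit: FAModelFit, gamma_acov: np.ndarray | None = None):
    """Scale-and-shift statistic matching the chi-square mean and variance.

    T_MV = T/a + b with a = sqrt(tr((U Gamma)^2)/df) and b = df - tr(U Gamma)/a,
    so E[T_MV] = df and Var[T_MV] = 2 df under the model.
    """
    UG = _ugamma(fit, gamma_acov)
    tr1 = float(np.trace(UG))
    tr2 = float(np.trace(UG @ UG))
    a = np.sqrt(tr2 / fit.df)
    if a <= 0:
        raise ValueError("non-positive scaling constant a; pathological Gamma")
    b = fit.df - tr1 / a
    T_MV = fit.chisq / a + b
    p = float(chi2.sf(T_MV, fit.df))
    fit.scaling.update({"a": a, "b": b, "T_MV": T_MV})
    return T_MV, a, b, p


def scaled_chisq_difference(T0, c0, df0, T1, c1, df1):
    """Satorra-Bentler scaled difference between nested fits (model 0 restrictive)."""
    if df0 <= df1:
        raise ValueError("model 0 must be the more restrictive model (df0 > df1)")
    df_diff = df0 - df1
    c_d = (c0 * df0 - c1 * df1) / df_diff
    fallback = c_d <= 0
    if fallback:
        c_d = 1.0
    dT = (T0 - T1) / c_d
    p = float(chi2.sf(max(dT, 0.0), df_diff))
    return dT, df_diff, p, fallback


def scaled_shifted_difference(fit0: FAModelFit, fit1: FAModelFit,
                              gamma_acov: np.ndarray | None = None):
    """Scale-and-shift corrected chi-square difference for nested DWLS fits.

    The difference-projection matrix is M_d = U_0 - U_1; the difference
    statistic is corrected to match the chi-square mean and variance:
    dT = (T0 - T1)/a_d + b_d with a_d = sqrt(tr((M_d Gamma)^2)/df_d) and
    b_d = df_d - tr(M_d Gamma)/a_d.  This is the form of difference test the
    reference WLSMV software applies to its scale-shifted statistics.
    """
    if fit0.df <= fit1.df:
        raise ValueError("fit0 must be the more restrictive model")
    gamma = gamma_acov if gamma_acov is not None else fit0.extras.get("gamma")
    for f in (fit0, fit1):
        if "U" not in f.extras:
            _ugamma(f, gamma)
    df_d = fit0.df - fit1.df
    MG = (fit0.extras["U"] - fit1.extras["U"]) @ gamma
    tr1 = float(np.trace(MG))
    tr2 = float(np.trace(MG @ MG))
    fallback = tr2 <= 0
    if fallback:
        a_d, b_d = 1.0, 0.0
    else:
        a_d = np.sqrt(tr2 / df_d)
        b_d = df_d - tr1 / a_d
    dT = (fit0.chisq - fit1.chisq) / a_d + b_d
    p = float(chi2.sf(max(dT, 0.0), df_d))
    return dT, df_d, p, fallback


def population_discrepancy(Sigma_true: np.ndarray, k: int, N: int | None = None) -> PopulationAnalysis:
    """Population ML discrepancy F0, RMSEA and noncentrality of a k-factor fit."""
    Sigma_true = np.asarray(Sigma_true, float)
    p = Sigma_true.shape[0]
    df = efa_df(p, k)
    if k == 0:
        fit_F = ml_factor_fit(Sigma_true, 0, n=2).F_min
    else:
        _, _, fit_F, _, _ = _ml_profile_fit(Sigma_true, k)
    F0 = max(fit_F, 0.0)
    rmsea = float(np.sqrt(F0 / df)) if df > 0 else 0.0
    delta = N * F0 if N is not None else None
    return PopulationAnalysis(F0=F0, df=df, rmsea=rmsea, delta=delta)


# ---------------------------------------------------------------------------
# sklearn-style estimators
# ---------------------------------------------------------------------------


class MLFactorAnalysis(BaseEstimator):
    """Normal-theory ML exploratory factor analysis (sklearn-style).

    Fits the Pearson correlation matrix of ``X`` by default; with
    ``standardize=False`` the sample covariance matrix is used, and robust
    (Satorra-Bentler) corrections based on empirical fourth moments become
    available through ``mean_corrected_``/``mean_variance_corrected_``.
    """

    def __init__(self, n_factors: int = 1, chisq_multiplier: str = "n",
                 standardize: bool = True, robust: bool = False):
        self.n_factors = n_factors
        self.chisq_multiplier = chisq_multiplier
        self.standardize = standardize
        self.robust = robust

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        n, p = X.shape
        if self.standardize:
            S = np.corrcoef(X, rowvar=False)
        else:
            S = np.cov(X, rowvar=False)
        fit = ml_factor_fit(S, self.n_factors, n, self.chisq_multiplier)
        if self.robust:
            _attach_ml_robust(fit, X, S)
            T_M, c, p_M = mean_corrected_statistic(fit)
            T_MV, a, b, p_MV = mean_variance_corrected_statistic(fit)
            self.scaling_ = dict(fit.scaling)
            self.p_value_robust_ = p_M
        self.fit_ = fit
        self.loadings_ = fit.loadings
        self.uniquenesses_ = fit.uniquenesses
        self.chisq_ = fit.chisq
        self.df_ = fit.df
        self.p_value_ = fit.p_value
        self.converged_ = fit.converged
        self.heywood_ = fit.heywood
        return self


def _vech_indices(p: int):
    return np.tril_indices(p)


def _attach_ml_robust(fit: FAModelFit, X: np.ndarray, S: np.ndarray) -> None:
    """Attach Gamma (ADF fourth moments), Delta and the normal-theory weight.

    Works on the vech (lower-triangle incl. diagonal) of the covariance
    structure, the standard setting for Satorra-Bentler corrections to ML.
    """
    n, p = X.shape
    rows, cols = _vech_indices(p)
    Z = X - X.mean(axis=0)
    prod = Z[:, rows] * Z[:, cols]  # n x q
    Wv = prod - prod.mean(axis=0)
    gamma = Wv.T @ Wv / n
    # normal-theory ML weight: inverse of the normality-implied covariance of
    # vech(S), Gamma_N[(ij),(kl)] = s_ik s_jl + s_il s_jk
    q = len(rows)
    gamma_n = np.empty((q, q))
    for a_idx in range(q):
        i, j = rows[a_idx], cols[a_idx]
        gamma_n[a_idx, :] = S[i, rows] * S[j, cols] + S[i, cols] * S[j, rows]
    V = np.linalg.inv(gamma_n)
    lam, psi = fit.loadings, fit.uniquenesses
    k = fit.k
    npar = p * k + p
    delta = np.zeros((q, npar))
    for f in range(k):
        for j in range(p):
            dS = np.zeros((p, p))
            dS[j, :] += lam[:, f]
            dS[:, j] += lam[:, f]
            delta[:, j * k + f] = dS[rows, cols]
    for j in range(p):
        col = np.zeros(q)
        col[(rows == j) & (cols == j)] = 1.0
        delta[:, p * k + j] = col
    fit.extras.update({"gamma": gamma, "delta": delta, "weight_full": V})


class DWLSFactorAnalysis(BaseEstimator):
    """WLSMV: DWLS factor analysis of polychoric correlations (sklearn-style).

    ``fit`` accepts an ordinal data matrix (categories 0..K-1), estimates the
    polychoric correlations with asymptotic covariance, fits the model by
    DWLS, and computes the Satorra-Bentler mean and mean-and-variance
    corrected statistics.  ``fit_from_polychoric`` skips the first step.
    """

    def __init__(self, n_factors: int = 1):
        self.n_factors = n_factors

    def fit(self, X, y=None):
        poly = polychoric_matrix(np.asarray(X), compute_acov=True)
        return self.fit_from_polychoric(poly)

    def fit_from_polychoric(self, poly: PolychoricResult):
        fit = dwls_fit(poly, self.n_factors)
        T_M, c, p_M = mean_corrected_statistic(fit)
        T_MV, a, b, p_MV = mean_variance_corrected_statistic(fit)
        self.fit_ = fit
        self.poly_ = poly
        self.loadings_ = fit.loadings
        self.uniquenesses_ = fit.uniquenesses
        self.chisq_ = fit.chisq
        self.df_ = fit.df
        self.T_M_, self.c_, self.p_value_mean_ = T_M, c, p_M
        self.T_MV_, self.a_, self.b_, self.p_value_ = T_MV, a, b, p_MV
        self.converged_ = fit.converged
        self.heywood_ = fit.heywood
        return self
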