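"""Factor-number decision rules and the empirical proportion of samples (EPS).

A "retention" means deciding in favor of the (true) one-factor model.  For
test-based methods the rule is the smallest k whose fit statistic is
non-significant; for difference-based methods (dT_M, GRM) the rule is a
non-significant 1- vs 2-factor comparison; parallel analysis counts observed
correlation eigenvalues exceeding a null-resampling quantile.  1 - EPS on
true one-factor data is the empirical Type-I error of the rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import factor_models as fm
from . import grm as grm_mod
from .correlations import PolychoricResult, polychoric_matrix

__all__ = [
    "DecisionRecord",
    "sequential_chisq_selection",
    "retain_one_factor_difference",
    "parallel_analysis",
    "eps",
    "ParallelAnalysis",
    "max_feasible_factors",
]


@dataclass
class DecisionRecord:
    """Outcome of one factor-number decision on one sample."""

    method: str
    n_factors: int | None
    retained_one: bool | None
    p_value: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def missing(self) -> bool:
        return self.retained_one is None


def max_feasible_factors(p: int) -> int:
    """Largest k with a non-negative exploratory-model df."""
    k = 0
    while ((p - (k + 1)) ** 2 - (p + k + 1)) / 2 >= 0:
        k += 1
    return k


def _fit_for_method(method: str, k: int, R=None, n=None, poly=None,
                    chisq_multiplier: str = "n", dwls_cache: dict | None = None):
    """Fit one k-factor model and return (p_value, fit)."""
    if method == "FA":
        fit = fm.ml_factor_fit(R, k, n, chisq_multiplier)
        return fit.p_value, fit
    if method == "FAC":
        fit = fm.ml_factor_fit(poly.rho_matrix, k, poly.n, chisq_multiplier,
                               method_label="FAC-ML")
        return fit.p_value, fit
    if method == "WLSMV":
        if dwls_cache is not None and k in dwls_cache:
            fit = dwls_cache[k]
        else:
            fit = fm.dwls_fit(poly, k)
            fm.mean_corrected_statistic(fit)
            fm.mean_variance_corrected_statistic(fit)
            if dwls_cache is not None:
                dwls_cache[k] = fit
        return _tmv_p(fit), fit
    raise ValueError(f"unknown sequential method {method!r}")


def _tmv_p(fit):
    from scipy.stats import chi2

    return float(chi2.sf(fit.scaling["T_MV"], fit.df))


def sequential_chisq_selection(
    data: np.ndarray | None = None,
    method: str = "FA",
    alpha: float = 0.05,
    max_k: int | None = None,
    poly: PolychoricResult | None = None,
    chisq_multiplier: str = "n",
    dwls_cache: dict | None = None,
) -> DecisionRecord:
    """Smallest k whose chi-square (robust for WLSMV) is non-significant.

    ``method`` is one of FA (Pearson + normal-theory ML), FAC (ML on the
    polychoric matrix) or WLSMV (DWLS + T_MV).  For FA pass the raw data; for
    the polychoric methods pass a fitted :class:`PolychoricResult` (or raw
    ordinal data, from which one is computed).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    method = method.upper()
    R = n = None
    if method == "FA":
        if data is None:
            raise ValueError("FA needs raw data")
        R = np.corrcoef(data, rowvar=False)
        n, p = data.shape
    else:
        if poly is None:
            poly = polychoric_matrix(np.asarray(data), compute_acov=(method == "WLSMV"))
        p = poly.rho_matrix.shape[0]
    if max_k is None:
        max_k = max_feasible_factors(p)
    flags: list[str] = []
    n_errors = 0
    for k in range(1, max_k + 1):
        try:
            pval, fit = _fit_for_method(method, k, R=R, n=n, poly=poly,
                                        chisq_multiplier=chisq_multiplier,
                                        dwls_cache=dwls_cache)
        except Exception as e:  # noqa: BLE001 - recorded, not fatal
            flags.append(f"k={k}:error:{type(e).__name__}")
            n_errors += 1
            continue
        if not fit.converged:
            flags.append(f"k={k}:nonconvergent")
        if pval > alpha:
            return DecisionRecord(method, k, k == 1, pval, flags)
    if n_errors == max_k:
        return DecisionRecord(method, None, None, None, flags + ["all-fits-failed"])
    flags.append("max_k-reached")
    return DecisionRecord(method, max_k, False, None, flags)


def retain_one_factor_difference(
    data: np.ndarray | None = None,
    method: str = "dT_M",
    alpha: float = 0.05,
    poly: PolychoricResult | None = None,
    dwls_cache: dict | None = None,
    grm_kwargs: dict | None = None,
) -> DecisionRecord:
    """Retain one factor iff the 1- vs 2-factor difference test is non-significant."""
    method_u = method.upper().replace("_", "")
    flags: list[str] = []
    try:
        if method_u == "DTM":
            if poly is None:
                poly = polychoric_matrix(np.asarray(data), compute_acov=True)
            fits = {}
            for k in (1, 2):
                if dwls_cache is not None and k in dwls_cache:
                    fits[k] = dwls_cache[k]
                else:
                    fits[k] = fm.dwls_fit(poly, k)
                    fm.mean_corrected_statistic(fits[k])
                    fm.mean_variance_corrected_statistic(fits[k])
                    if dwls_cache is not None:
                        dwls_cache[k] = fits[k]
                if not fits[k].converged:
                    flags.append(f"k={k}:nonconvergent")
            dT, df_diff, p, fallback = fm.scaled_chisq_difference(
                fits[1].chisq, fits[1].scaling["c"], fits[1].df,
                fits[2].chisq, fits[2].scaling["c"], fits[2].df,
            )
            if fallback:
                flags.append("unscaled-difference-fallback")
            return DecisionRecord("dT_M", 1 if p > alpha else 2, p > alpha, p, flags)
        if method_u == "GRM":
            kw = dict(grm_kwargs or {})
            fit1 = grm_mod.grm_fit_em(data, k=1, **kw)
            fit2 = grm_mod.grm_fit_em(data, k=2, init=(fit1.slopes, fit1.bounds), **kw)
            for k, f in ((1, fit1), (2, fit2)):
                if not f.converged:
                    flags.append(f"k={k}:nonconvergent")
            _, _, p = grm_mod.grm_lrt(fit1, fit2)
            return DecisionRecord("GRM", 1 if p > alpha else 2, p > alpha, p, flags)
    except Exception as e:  # noqa: BLE001
        return DecisionRecord(method, None, None, None, flags + [f"error:{type(e).__name__}"])
    raise ValueError(f"unknown difference method {method!r}")


def _corr_eigvals(data: np.ndarray, engine: str, basis: str = "pc") -> np.ndarray:
    if engine == "pearson":
        R = np.corrcoef(data, rowvar=False)
    elif engine == "polychoric":
        R = polychoric_matrix(data, compute_acov=False).rho_matrix
    else:
        raise ValueError("engine must be 'pearson' or 'polychoric'")
    if basis == "reduced":
        # common-factor variant: diagonal replaced by squared multiple correlations
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
        R = R.copy()
        np.fill_diagonal(R, smc)
    elif basis != "pc":
        raise ValueError("basis must be 'pc' or 'reduced'")
    return np.sort(np.linalg.eigvalsh(R))[::-1]


def parallel_analysis(
    data: np.ndarray,
    engine: str = "pearson",
    n_resamples: int = 100,
    criterion_quantile: float = 0.95,
    seed=0,
    null: str = "permutation",
    criterion: str = "quantile",
    basis: str = "pc",
) -> DecisionRecord:
    """Horn-style parallel analysis.

    Counts leading observed-correlation eigenvalues exceeding the rank-matched
    criterion from null data, stopping at the first failure.  Defaults: null
    data by independent column permutations (marginals preserved), the 95th
    percentile criterion, and full correlation (principal-component)
    eigenvalues.  The null (``'normal'`` simulates uncorrelated Gaussian
    data), the criterion (``'mean'``), and the eigenvalue basis
    (``'reduced'``: diagonal replaced by squared multiple correlations) are
    configurable because published parallel-analysis implementations differ
    in exactly these choices.
    """
    if n_resamples < 20:
        raise ValueError("n_resamples must be >= 20")
    data = np.asarray(data)
    rng = np.random.default_rng(seed)
    flags: list[str] = []
    obs = _corr_eigvals(data, engine, basis)
    null_eigs = np.empty((n_resamples, data.shape[1]))
    for s in range(n_resamples):
        if null == "normal":
            perm = rng.standard_normal(data.shape)
        elif null == "permutation":
            perm = np.column_stack(
                [data[rng.permutation(data.shape[0]), j] for j in range(data.shape[1])]
            )
        else:
            raise ValueError("null must be 'permutation' or 'normal'")
        try:
            null_eigs[s] = _corr_eigvals(perm, engine if null == "permutation" else "pearson", basis)
        except Exception as e:  # noqa: BLE001 - degenerate polychoric resample
            flags.append(f"resample{s}:error:{type(e).__name__}")
            null_eigs[s] = np.nan
    if criterion == "mean":
        thresh = np.nanmean(null_eigs, axis=0)
    elif criterion == "quantile":
        thresh = np.nanquantile(null_eigs, criterion_quantile, axis=0)
    else:
        raise ValueError("criterion must be 'quantile' or 'mean'")
    n_factors = 0
    for lam_obs, lam_null in zip(obs, thresh):
        if lam_obs > lam_null:
            n_factors += 1
        else:
            break
    name = "PA" if engine == "pearson" else "CPA"
    return DecisionRecord(name, n_factors, n_factors == 1, None, flags)


def eps(decisions) -> float:
    """Empirical proportion of samples in which the one-factor model is retained."""
    decisions = list(decisions)
    if not decisions:
        raise ValueError("no decisions")
    kept = [d.retained_one for d in decisions if d.retained_one is not None]
    if not kept:
        raise ValueError("all decisions missing")
    return float(np.mean(kept))


class ParallelAnalysis(BaseEstimator):
    """Parallel analysis as an sklearn-style estimator.

    Attributes after ``fit``: ``n_factors_``, ``retained_one_``.
    """

    def __init__(self, engine: str = "pearson", n_resamples: int = 100,
                 criterion_quantile: float = 0.95, random_state=0,
                 null: str = "permutation", criterion: str = "quantile",
                 basis: str = "pc"):
        self.engine = engine
        self.n_resamples = n_resamples
        self.criterion_quantile = criterion_quantile
        self.random_state = random_state
        self.null = null
        self.criterion = criterion
        self.basis = basis

    def fit(self, X, y=None):
        rec = parallel_analysis(
            np.asarray(X), self.engine, self.n_resamples,
            self.criterion_quantile, self.random_state,
            null=self.null, criterion=self.criterion, basis=self.basis,
        )
        self.record_ = rec
        self.n_factors_ = rec.n_factors
        self.retained_one_ = rec.retained_one
        return self
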