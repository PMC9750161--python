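"""Monte Carlo harness: run the condition grid and aggregate the results.

The study grid crosses sample size N in {100, 500}, number of items p in
{6, 12}, thresholds r in {1, 2, 4}, loading in {0.6, 0.9} and five skewness
patterns -- 120 conditions.  Each replicate is generated, analyzed by the
requested methods, and appended to a tidy long-format table, the single
source of truth from which EPS tables, ANOVA effect sizes and recovery RMSEs
are derived.

Seeding: replicate (i, j) of condition c uses SeedSequence([master, c, j]),
so any replicate is reproducible in isolation and results are independent of
the worker count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dimensionality as dim
from . import grm as grm_mod
from .correlations import polychoric_matrix
from .synthetic_data import generate_condition_sample

__all__ = [
    "SimulationCondition",
    "expand_grid",
    "run_grid",
    "summarize_eps",
    "anova_partial_eta",
    "rmse_recovery",
    "METHODS",
    "TABLE_LAYOUTS",
]

GRID_LEVELS = {
    "N": (100, 500),
    "p": (6, 12),
    "r": (1, 2, 4),
    "loading": (0.6, 0.9),
    "skew_pattern": ("None", "SP", "MM", "SM", "N+SM"),
}

METHODS = ("pa", "fa", "wlsmv", "dtm", "cpa", "fac", "grm")

#: presets reproducing the published table layouts (within p = 6 or 12)
TABLE_LAYOUTS = {
    "table3": (6, ["linear_model", "skew_pattern", "loading"]),
    "table4": (12, ["linear_model", "skew_pattern", "loading"]),
    "table5": (6, ["linear_model", "skew_pattern", "N"]),
    "table6": (12, ["linear_model", "skew_pattern", "N"]),
    "table7": (6, ["linear_model", "skew_pattern", "r"]),
    "table8": (12, ["linear_model", "skew_pattern", "r"]),
    "overall": (None, []),
}


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the study grid."""

    N: int
    p: int
    r: int
    loading: float
    skew_pattern: str

    @property
    def condition_id(self) -> str:
        return f"N{self.N}_p{self.p}_r{self.r}_l{self.loading:g}_{self.skew_pattern}"

    @property
    def linear_model_true(self) -> bool:
        # the linear FA structure holds when all items share one threshold set
        return self.skew_pattern in ("None", "SP")


def expand_grid(**overrides) -> list[SimulationCondition]:
    """Fully crossed condition grid (120 cells by default).

    Keyword overrides restrict a dimension, e.g. ``expand_grid(p=[6])``.
    """
    levels = {k: tuple(overrides.get(k, v)) for k, v in GRID_LEVELS.items()}
    return [
        SimulationCondition(N=n, p=p, r=r, loading=lam, skew_pattern=sk)
        for n, p, r, lam, sk in itertools.product(*levels.values())
    ]


def _analyze_sample(ds, methods, alpha, pa_resamples, pa_quantile, grm_kwargs,
                    seeds, store_estimates):
    """Apply the requested decision methods to one generated sample."""
    need_poly = any(m in methods for m in ("fac", "wlsmv", "dtm"))
    need_acov = any(m in methods for m in ("wlsmv", "dtm"))
    poly = None
    if need_poly:
        try:
            poly = polychoric_matrix(ds.data, compute_acov=need_acov)
        except Exception:  # noqa: BLE001 - flagged per method below
            poly = None
    dwls_cache: dict = {}
    records, estimates = [], []
    grm_fit1 = None
    for m in methods:
        if m == "fa":
            rec = dim.sequential_chisq_selection(ds.data, method="FA", alpha=alpha)
        elif m == "fac":
            rec = (dim.sequential_chisq_selection(ds.data, method="FAC", alpha=alpha, poly=poly)
                   if poly is not None else dim.DecisionRecord("FAC", None, None, None, ["polychoric-failed"]))
        elif m == "wlsmv":
            rec = (dim.sequential_chisq_selection(ds.data, method="WLSMV", alpha=alpha,
                                                  poly=poly, dwls_cache=dwls_cache)
                   if poly is not None else dim.DecisionRecord("WLSMV", None, None, None, ["polychoric-failed"]))
        elif m == "dtm":
            rec = (dim.retain_one_factor_difference(ds.data, method="dT_M", alpha=alpha,
                                                    poly=poly, dwls_cache=dwls_cache)
                   if poly is not None else dim.DecisionRecord("dT_M", None, None, None, ["polychoric-failed"]))
        elif m == "grm":
            kw = dict(grm_kwargs or {})
            try:
                grm_fit1 = grm_mod.grm_fit_em(ds.data, k=1, **kw)
                fit2 = grm_mod.grm_fit_em(ds.data, k=2,
                                          init=(grm_fit1.slopes, grm_fit1.bounds), **kw)
                _, _, pval = grm_mod.grm_lrt(grm_fit1, fit2)
                rec = dim.DecisionRecord("GRM", 1 if pval > alpha else 2, pval > alpha, pval)
            except Exception as e:  # noqa: BLE001
                rec = dim.DecisionRecord("GRM", None, None, None, [f"error:{type(e).__name__}"])
        elif m == "pa":
            rec = dim.parallel_analysis(ds.data, "pearson", pa_resamples, pa_quantile,
                                        seed=seeds["pa"])
        elif m == "cpa":
            try:
                rec = dim.parallel_analysis(ds.data, "polychoric", pa_resamples,
                                            pa_quantile, seed=seeds["cpa"])
            except Exception as e:  # noqa: BLE001
                rec = dim.DecisionRecord("CPA", None, None, None, [f"error:{type(e).__name__}"])
        else:
            raise ValueError(f"unknown method {m!r}")
        records.append((m, rec))

        if store_estimates:
            est = _k1_estimates(m, ds, poly, dwls_cache, grm_fit1)
            if est is not None:
                estimates.append(est)
    return records, estimates


def _k1_estimates(m, ds, poly, dwls_cache, grm_fit1):
    """One-factor parameter estimates for the recovery study."""
    from . import factor_models as fm

    tau_true = [list(t.thresholds) for t in ds.thresholds]
    base = {
        "lambda_true": list(ds.loadings),
        "tau_true": tau_true,
    }
    try:
        if m == "fa":
            fit = fm.ml_factor_fit(np.corrcoef(ds.data, rowvar=False), 1, ds.spec.n)
            return {**base, "method": m, "lambda_hat": list(fit.loadings[:, 0]),
                    "psi_hat": list(fit.uniquenesses), "tau_hat": None}
        if m == "fac" and poly is not None:
            fit = fm.ml_factor_fit(poly.rho_matrix, 1, poly.n, method_label="FAC-ML")
            return {**base, "method": m, "lambda_hat": list(fit.loadings[:, 0]),
                    "psi_hat": list(fit.uniquenesses),
                    "tau_hat": [list(t) for t in poly.thresholds_hat]}
        if m == "wlsmv" and poly is not None:
            fit = dwls_cache.get(1) or fm.dwls_fit(poly, 1)
            return {**base, "method": m, "lambda_hat": list(fit.loadings[:, 0]),
                    "psi_hat": list(fit.uniquenesses),
                    "tau_hat": [list(t) for t in poly.thresholds_hat]}
        if m == "grm" and grm_fit1 is not None:
            lam, taus = grm_mod.irt_to_fa(grm_fit1.slopes, grm_fit1.bounds)
            return {**base, "method": m, "lambda_hat": list(lam[:, 0]),
                    "psi_hat": list(1.0 - lam[:, 0] ** 2),
                    "tau_hat": [list(t) for t in taus]}
    except Exception:  # noqa: BLE001
        return None
    return None


def run_grid(
    grid=None,
    methods=("fa", "pa"),
    replicates: int = 100,
    master_seed: int = 0,
    alpha: float = 0.05,
    pa_resamples: int = 100,
    pa_quantile: float = 0.95,
    grm_kwargs: dict | None = None,
    store_estimates: bool = False,
    workers: int = 1,
    progress=None,
):
    """Run the simulation grid; returns a tidy results DataFrame.

    With ``store_estimates=True`` returns ``(results, estimates)`` where the
    second frame holds one-factor parameter estimates for the recovery study.
    Per-replicate failures are recorded as missing decisions, never raised.
    """
    if grid is None:
        grid = expand_grid()
    methods = tuple(m.lower() for m in methods)
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")

    def _one_condition(ci, cond):
        rows, est_rows = [], []
        for rep in range(replicates):
            seq = np.random.SeedSequence([int(master_seed), ci, rep])
            data_seed, pa_seed, cpa_seed = seq.spawn(3)
            ds = generate_condition_sample(cond, seed=data_seed)
            recs, ests = _analyze_sample(
                ds, methods, alpha, pa_resamples, pa_quantile, grm_kwargs,
                seeds={"pa": pa_seed, "cpa": cpa_seed},
                store_estimates=store_estimates,
            )
            meta = {
                "condition_id": cond.condition_id, "N": cond.N, "p": cond.p,
                "r": cond.r, "loading": cond.loading,
                "skew_pattern": cond.skew_pattern,
                "linear_model": cond.linear_model_true, "replicate": rep,
            }
            for m, rec in recs:
                rows.append({**meta, "method": m, "n_factors": rec.n_factors,
                             "retained": rec.retained_one, "p_value": rec.p_value,
                             "flags": ";".join(rec.flags)})
            for est in ests:
                est_rows.append({**meta, **est})
        return rows, est_rows

    if workers and workers > 1:
        from joblib import Parallel, delayed

        out = Parallel(n_jobs=workers)(
            delayed(_one_condition)(ci, cond) for ci, cond in enumerate(grid)
        )
    else:
        out = []
        for ci, cond in enumerate(grid):
            out.append(_one_condition(ci, cond))
            if progress is not None:
                progress(ci, len(grid))

    rows = [r for rws, _ in out for r in rws]
    est_rows = [e for _, ests in out for e in ests]
    results = pd.DataFrame(rows).sort_values(
        ["condition_id", "replicate", "method"], kind="stable"
    ).reset_index(drop=True)
    if store_estimates:
        return results, pd.DataFrame(est_rows)
    return results


def summarize_eps(results: pd.DataFrame, grouping="overall", pivot: bool = False) -> pd.DataFrame:
    """EPS per group x method, with Monte Carlo standard errors.

    ``grouping`` is a table-layout preset name or an explicit list of result
    columns.  Cells pool simple proportions over the non-displayed grid
    dimensions.
    """
    df = results.copy()
    if "linear_model" not in df.columns:
        df["linear_model"] = df["skew_pattern"].isin(["None", "SP"])
    if isinstance(grouping, str):
        if grouping not in TABLE_LAYOUTS:
            raise KeyError(f"unknown layout {grouping!r}; one of {sorted(TABLE_LAYOUTS)}")
        p_filter, keys = TABLE_LAYOUTS[grouping]
        if p_filter is not None:
            df = df[df["p"] == p_filter]
    else:
        keys = list(grouping)
        unknown = set(keys) - set(df.columns)
        if unknown:
            raise KeyError(f"unknown grouping columns {sorted(unknown)}")
    if df.empty:
        raise ValueError("no results after filtering")

    def _agg(g):
        kept = g["retained"].dropna()
        n_eff = len(kept)
        e = kept.mean() if n_eff else np.nan
        return pd.Series({
            "eps": e,
            "n_effective": n_eff,
            "n_missing": int(g["retained"].isna().sum()),
            "mc_se": np.sqrt(e * (1 - e) / n_eff) if n_eff else np.nan,
        })

    by = keys + ["method"]
    out = df.groupby(by, dropna=False, observed=True).apply(_agg, include_groups=False).reset_index()
    if pivot:
        order = [m for m in ("pa", "fa", "wlsmv", "dtm", "cpa", "fac", "grm")
                 if m in out["method"].unique()]
        out = out.pivot_table(index=keys or None, columns="method", values="eps")[order]
    return out


def anova_partial_eta(
    results: pd.DataFrame,
    method: str,
    factors=("N", "p", "r", "loading", "skew_pattern"),
    max_interaction_order: int = 2,
    eps_clip: float = 1e-12,
) -> pd.DataFrame:
    """Factorial ANOVA of logit(p-value) with partial-eta-squared effect sizes."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = results[results["method"] == method.lower()].copy()
    df = df.dropna(subset=["p_value"])
    if df.empty:
        raise ValueError(f"no p-values for method {method!r}")
    pv = df["p_value"].clip(eps_clip, 1 - eps_clip)
    df["logit_p"] = np.log(pv / (1 - pv))
    factors = [f for f in factors if df[f].nunique() > 1]
    if not factors:
        raise ValueError("no factor varies in the supplied results")
    terms = " + ".join(f"C({f})" for f in factors)
    formula = f"logit_p ~ ({terms}) ** {max_interaction_order}" if len(factors) > 1 else f"logit_p ~ {terms}"
    if df["logit_p"].var() < 1e-24:
        # constant response: every effect explains nothing
        names = []
        import itertools as it

        for order in range(1, max_interaction_order + 1):
            for combo in it.combinations(factors, order):
                names.append(":".join(f"C({f})" for f in combo))
        return pd.DataFrame({"term": names, "sum_sq": 0.0, "df": np.nan,
                             "partial_eta2": 0.0})
    model = smf.ols(formula, data=df).fit()
    try:
        table = sm.stats.anova_lm(model, typ=2)
    except Exception:
        table = sm.stats.anova_lm(model, typ=1)
    ss_err = float(table.loc["Residual", "sum_sq"])
    out = table.drop(index="Residual").copy()
    denom = out["sum_sq"] + ss_err
    out["partial_eta2"] = np.where(out["sum_sq"] <= 1e-12, 0.0,
                                   out["sum_sq"] / np.where(denom > 0, denom, 1.0))
    return out.reset_index().rename(columns={"index": "term"})


def rmse_recovery(estimates: pd.DataFrame, by=("condition_id",)) -> pd.DataFrame:
    """RMSE of one-factor parameter estimates, per group x method x class.

    Loading signs are aligned to the truth (the whole vector is flipped when
    the mean product with the true loadings is negative) before the RMSE.
    Threshold RMSE skips items whose estimated threshold count differs from
    the truth (category collapses); the skip count is reported.
    """
    rows = []
    for key_vals, g in estimates.groupby(list(by) + ["method"], observed=True):
        *gv, method = key_vals if isinstance(key_vals, tuple) else (key_vals,)
        sq = {"lambda": [], "psi": [], "tau": []}
        tau_skipped = 0
        for _, row in g.iterrows():
            lam_t = np.asarray(row["lambda_true"], float)
            lam_h = np.asarray(row["lambda_hat"], float)
            if np.mean(lam_h * lam_t) < 0:
                lam_h = -lam_h
            sq["lambda"].extend((lam_h - lam_t) ** 2)
            psi_t = 1.0 - lam_t**2
            sq["psi"].extend((np.asarray(row["psi_hat"], float) - psi_t) ** 2)
            if row.get("tau_hat") is not None:
                for th, tt in zip(row["tau_hat"], row["tau_true"]):
                    if len(th) == len(tt):
                        sq["tau"].extend((np.asarray(th) - np.asarray(tt)) ** 2)
                    else:
                        tau_skipped += 1
        for cls, vals in sq.items():
            if vals:
                rows.append({**dict(zip(by, gv)), "method": method,
                             "parameter_class": cls,
                             "rmse": float(np.sqrt(np.mean(vals))),
                             "n_terms": len(vals),
                             "tau_items_skipped": tau_skipped if cls == "tau" else 0})
    return pd.DataFrame(rows)
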