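# overfactor

How many latent factors does skewed rating-scale data support? When Likert or
rating items pile up near one end of the scale, the Pearson correlations
between them are *attenuated* — most severely between items skewed in
opposite directions — and the classical maximum-likelihood factor-analysis
(FA) chi-square then retains too many factors. `overfactor` implements the
full toolkit needed to study (and avoid) this overfactoring problem:

* a **data generator** for one-factor ordinal data with exactly prescribed
  item skewness γ, via binomial marginals: the binomial success probability

  π = 1/2 − γ√r / √(16 + 4γ²r)

  (r = number of thresholds) gives Binomial(r, π) skewness exactly γ; the
  thresholds are the standard-normal deviates of its cumulative
  probabilities, so discretizing a unit-variance latent response
  y\*ᵢⱼ = λⱼξᵢ + eᵢⱼ yields items with the target skewness and a clean
  one-factor structure underneath;
* **polychoric/tetrachoric correlations** (two-step ML with Owen's-T exact
  bivariate-normal rectangles) together with the asymptotic covariance Γ̂ of
  the estimates from per-observation influence functions;
* **factor models**: ML exploratory FA of a correlation/covariance matrix
  (uniqueness-profile algorithm, F(S,Σ) = log|Σ| − log|S| + tr(SΣ⁻¹) − p,
  X² = N·F), and DWLS/WLSMV on polychorics with the Satorra–Bentler
  mean-corrected statistic T_M = T/c, the mean-and-variance corrected
  T_MV = T/a + b, and the scaled chi-square difference dT_M;
* **Samejima's graded response model** (GRM) by marginal-ML EM with
  Gauss–Hermite quadrature, cumulative logits
  P\*(y ≥ t|θ) = logistic(a'θ − b_t), and the IRT↔FA conversion
  λ = a\*/√(1+‖a\*‖²), a\* = a/1.702;
* **dimensionality rules**: sequential chi-square selection, 1-vs-2-factor
  difference tests, Horn-style parallel analysis (Pearson or polychoric);
* a **Monte Carlo harness** that runs the 120-condition study grid
  (N ∈ {100,500} × p ∈ {6,12} × r ∈ {1,2,4} × λ ∈ {0.6,0.9} × five skew
  patterns), summarizes the empirical proportion of samples retaining one
  factor (EPS), fits partial-η² ANOVAs to logit p-values, and computes
  parameter-recovery RMSEs.

The estimators are scikit-learn style (`fit`, trailing-underscore
attributes, `get_params`), so they compose with sklearn tooling.

## A worked example

One sample from the hardest study cell — 6 items, 3 categories, loadings
0.9, half the items skewed −2 and half +2:

```python
import numpy as np
from overfactor import (MLFactorAnalysis, DWLSFactorAnalysis, ParallelAnalysis,
                        GradedResponseModel)
from overfactor.harness import SimulationCondition
from overfactor.synthetic_data import generate_condition_sample
from overfactor.dimensionality import retain_one_factor_difference

cond = SimulationCondition(N=500, p=6, r=2, loading=0.9, skew_pattern="SM")
ds = generate_condition_sample(cond, seed=7)

fa = MLFactorAnalysis(n_factors=1).fit(ds.data)
print(fa.chisq_, fa.df_, fa.p_value_)        # 395.3  9  0.0000
print(np.abs(fa.loadings_[:, 0]).round(2))   # [0.78 0.73 0.75 0.34 0.36 0.34]

w = DWLSFactorAnalysis(n_factors=1).fit(ds.data)
print(w.T_MV_, w.p_value_)                   # 4.6  0.868
print(np.abs(w.loadings_[:, 0]).round(2))    # [0.93 0.87 0.91 0.91 0.90 0.92]

print(ParallelAnalysis(random_state=0).fit(ds.data).n_factors_)   # 2
print(retain_one_factor_difference(ds.data, "dT_M").p_value)      # 0.998
print(np.abs(GradedResponseModel().fit(ds.data).loadings_[:, 0]).round(2))
                                             # [0.94 0.87 0.91 0.92 0.91 0.93]
```

The data are one-factor by construction, yet normal-theory FA rejects that
model outright (p ≈ 0) and splits the loadings by skew sign — the classic
"difficulty factor" artifact — and parallel analysis sees two factors.
WLSMV's corrected statistic retains one factor (p = 0.87), the scaled
difference test agrees (p = 0.998), and both WLSMV and the GRM recover the
true loading 0.9 almost exactly.

Full grid runs from the shell:

```bash
overfactor simulate --methods fa,wlsmv,dtm,pa --reps 100 --seed 1 --out results.csv
overfactor summarize --results results.csv --layout table3
overfactor anova --results results.csv --method fa
```

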