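# Methods

## The generating model

All simulated data come from a one-factor categorical factor model. Latent
responses are

y\*ᵢⱼ = λⱼ ξᵢ + eᵢⱼ,  ξᵢ ~ N(0,1),  eᵢⱼ ~ N(0, 1 − λⱼ²),

so each y\* is standard normal and thresholds live on the standard-normal
scale; this keeps the generator consistent with the polychoric metric and
with the tabulated thresholds. Observed categories are
yᵢⱼ = #{t : τⱼₜ < y\*ᵢⱼ}.

Item skewness is controlled through binomial marginals: for target skewness
γ and r thresholds, π = 1/2 − γ√r/√(16 + 4γ²r) makes Binomial(r, π) have
skewness exactly γ, and τₜ = Φ⁻¹(Pr(X ≤ t−1)), X ~ Binomial(r, π), makes the
marginal category distribution exactly that binomial. Both identities are
property-tested to 1e−10. Other threshold placements with the same γ exist;
this construction is the one the study grid tabulates.

Skew patterns assign γ to items in equal blocks (e.g. "SM" gives half the
items γ=−2 and half γ=+2); the equal split is a design choice — the pattern
labels do not prescribe one. Category labels are fixed 0..r even when a
sample leaves a category empty; estimators collapse empty categories
themselves and record the collapse.

Seeding: each replicate uses `SeedSequence([master, condition_index,
replicate])`, so any replicate is reproducible in isolation and results do
not depend on worker count.

## Polychoric correlations and their covariance

Two-step estimation: thresholds from inverse-normal marginal cumulative
proportions, then pairwise ML for ρ with thresholds fixed. Bivariate-normal
rectangle probabilities use Owen's T (machine-precision, vectorized);
infinite limits are clamped at ±8.5 SD (tail < 1e−16). Estimates at the
boundary are clamped at |ρ| = 1−1e−6 and flagged; non-positive-definite
matrices are smoothed by eigenvalue clipping at 1e−6 and re-normalized, and
the smoothing is recorded.

The asymptotic covariance Γ̂ of √n(ρ̂ − ρ) uses per-observation influence
functions with the threshold step profiled out via the information identity,
gᵢ = I_ρρ⁻¹(s_ρ,ᵢ − I_ρτ'ψ_τ,ᵢ). A purely empirical outer product
(1/n)Σgᵢgᵢ' fails in a specific, consequential way: with extreme opposite
thresholds and high ρ, most of the Fisher information sits in cells of
probability ~1e−5 that are never observed at n ≤ 500, so empirical variances
are biased downward several-fold and every Γ̂-based corrected statistic
over-rejects badly. The default estimator is therefore **hybrid**: the
diagonal is the model-implied influence variance (closed form from the
fitted bivariate cells, including the threshold-profiling terms), and
off-diagonals use the empirical correlations between influences scaled to
those variances. `acov_polychoric(..., method="empirical")` retains the
plain estimator. In benign cells the two coincide; in extreme cells the
hybrid is somewhat conservative (the corrected statistics under-reject
rather than over-reject), which we prefer for a dimensionality-retention
tool. Cells are floored at 1e−6 inside the influence computation so
near-boundary ρ̂ cannot produce numerically explosive scores.

## Factor models and robust statistics

ML exploratory FA minimizes F(S,Σ) = log|Σ| − log|S| + tr(SΣ⁻¹) − p by
profiling uniquenesses (eigen-decomposition inner step, analytic gradient,
L-BFGS-B in log ψ, ψ floored at 1e−4·diag with a Heywood flag). X² = N·F by
default; the Bartlett multiplier (n−1−(2p+5)/6−2k/3) is available as
configuration. The fit is verified against `statsmodels` ML factor analysis
to 4 decimals. df = [(p−k)² − (p+k)]/2.

DWLS ("WLSMV") minimizes (s−σ(Λ))' diag(Γ̂)⁻¹ (s−σ(Λ)) over the loading
matrix, with uniquenesses implied by the unit-diagonal correlation
structure. Corrections use U = W⁻¹ − W⁻¹Δ(Δ'W⁻¹Δ)⁺Δ'W⁻¹ (pseudo-inverse,
because exploratory Λ is rotation-deficient for k ≥ 2):

* T_M = T/c with c = tr(UΓ̂)/df;
* T_MV = T/a + b with a = √(tr((UΓ̂)²)/df), b = df − tr(UΓ̂)/a — this
  scale-and-shift form matches the published real-data table layout
  (T/a + b reproduces its printed values);
* dT_M = (T₀−T₁)/c_d, c_d = (c₀df₀ − c₁df₁)/(df₀−df₁), with an unscaled
  fallback (flagged) if c_d ≤ 0; a scale-and-shift difference
  (`scaled_shifted_difference`) is also provided.

The WLSMV retention decision uses the T_MV p-value: the raw DWLS statistic
is not chi-square distributed, and only the corrected statistic can produce
the near-nominal retention rates the method is known for.

For ML fits on continuous data, Satorra–Bentler corrections are available
with Γ̂ from empirical fourth moments on vech(S) and the normal-theory
weight as the inverse of the normality-implied covariance of vech(S); on
multivariate-normal data c ≈ 1 (tested).

Population analysis: `population_discrepancy` minimizes F against an
analytic Σ (built from the attenuation formulas) and returns F₀,
RMSEA = √(F₀/df) and noncentrality δ = N·F₀. With one shared threshold set
the one-factor linear structure is exact (F₀ = 0) and the fitted loading
satisfies λ_fit² = a·λ² with a the correlation attenuation factor; with
mixed skew F₀ > 0 — both are tested.

## Graded response model

Marginal-ML EM: the E-step weights unique response patterns over a
Gauss–Hermite grid (21 points for one factor, 15 per dimension for two); the
M-step maximizes each item's expected complete-data log-likelihood by
L-BFGS-B in a monotone parameterization of the bounds (b₁, log-gaps), so
category ordering can never be violated. k=2 exploratory fits use the
echelon identification (upper-triangle slopes fixed at 0) and are
warm-started from the nested one-factor solution with the new slope column
at 0.3; without the warm start, iteration-capped two-factor fits can end
below the one-factor log-likelihood and the LRT is undefined. `grm_lrt`
clips negative differences within 0.5 to zero (the larger model nests the
smaller, so the true difference is non-negative) and errors beyond that.

The logit link approximates the normal ogive through D = 1.702; the
conversion to the FA metric is λ = a\*/√(1+‖a\*‖²), τ = (b/D)/√(1+‖a\*‖²)
with a\* = a/D. The residual logit/probit gap is a small, known
inconsistency and is not corrected. The dimensionality decision is the
1-vs-2-factor LRT at α — the published study does not state its GRM
decision statistic, so this is an explicit assumption.

## Dimensionality rules and EPS

Sequential selection returns the smallest k whose statistic is
non-significant, capped at the largest k with df ≥ 0 (3 at p=6, 7 at p=12).
Parallel analysis defaults to column-permutation null data (marginals
preserved), the 95th-percentile criterion, and eigenvalues of the full
correlation matrix, counting the leading run of exceedances; the null
("normal"), criterion ("mean") and eigenvalue basis ("reduced": diagonal
replaced by squared multiple correlations) are configurable because
published implementations differ in exactly these choices and the choice
measurably shifts EPS. EPS is the mean retention over non-missing
replicates; 1−EPS is the empirical Type-I error on true one-factor data.
α = 0.05 throughout the simulation (configurable).

## Harness and problem sizes

The tidy long-format results table is the single source of truth; EPS
tables (in the published layouts), the logit-p partial-η² ANOVA
(`statsmodels` OLS + type-II ANOVA, p clamped to [1e−12, 1−1e−12]) and the
recovery RMSE tables are all derived from it. Per-replicate failures are
recorded as missing decisions, never raised. Default problem sizes are
chosen for a single CPU: the acceptance computations use 50
replicates/condition for grid-wide means and 100 replicates/sub-condition
for single cells (the GRM cell runs 25 replicates/sub-condition with an
11-point quadrature, as repeated two-factor EM fits dominate its cost);
Monte Carlo standard errors at these sizes are reported alongside every
EPS.

## What the generator does and does not emulate

It reproduces the study conditions exactly: binomial marginals, exact
underlying normality of latent responses and factor, equal loadings within
a condition. Real rating data violate several of these (non-normal latent
responses distort polychorics; loadings vary across items; extra minor
factors exist), so green tests here demonstrate correctness of the methods
under the model, not robustness beyond it.

## Known limitations

* Testing k vs k+1 factors is a boundary problem — the added factor's
  loadings are unidentified under the null — so even the exact
  normal-theory ML likelihood-ratio difference over-rejects relative to
  χ²(df_d) (measured ≈ 0.11 at α = 0.05, N = 500, p = 6 on continuous
  normal data). The scaled difference inherits this; its calibration is
  therefore judged against that oracle, not against the nominal α.
* In extreme mixed-skew cells the hybrid Γ̂ makes T_MV conservative
  (retention near 1 where sharper — but unstable — weightings would reject
  more).
* Joint (one-step) polychoric ML, full-weight WLS, MNCM estimation and
  non-normal latent densities are out of scope; the MNCM appears only as a
  parameter-count formula.
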