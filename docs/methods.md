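# Methods

## Models

All models describe the Hb level `y_it` (mmol/l) of donor i at their t-th
visit, per gender, with covariates `x_it = (Age_it, Season_it, DPV_it)`:
age in years, a warm-season indicator (spring/summer = 1), and DPV, the
indicator of a donation at the previous visit (0 at visit 1, since a donor's
first visit is a health check). Calendar time is not modelled; the sequential
visit number is the time axis.

**Pooled linear regression.** `y = α + β'x + ε`, ε iid N(0, σ²). Fitted by
OLS (statsmodels); kept as the benchmark that ignores within-donor
correlation.

**Transition model of order q.** The current Hb is regressed on covariates
and on the q previous *covariate-adjusted* values:

    y_it = α + β'x_it + Σ_{r=1..q} γ_r (y_{i,t−r} − β'x_{i,t−r}) + ε_it .

Writing `w = y − β'x`, w is an AR(q) with innovation variance σ²_ε,
stationary mean `μ_w = α/(1−Σγ_r)` and stationarity requiring the roots of
`1 − Σ γ_r z^r` outside the unit circle. Note the intercept is *not*
subtracted inside the lag terms, so the reported α is the stationary level
times `(1−Σγ)`, not the level itself; α and γ therefore trade off along a
likelihood ridge and α's standard error is correspondingly large while
`α/(1−Σγ)` is precisely determined.

The likelihood is exact: the centered series `z = w − μ_w` is put in
companion-form state space, the Kalman filter is started from the stationary
state covariance (the discrete-Lyapunov / Yule–Walker solution), and the
prediction-error decomposition is summed over donors. Donors with fewer than
q+1 visits contribute through the stationary marginal of their first
observations — no presample is discarded. Because the model is
time-invariant, the filter's innovation variances and gains are
data-independent; they are precomputed once per series length and applied to
all donors of that length as one vectorized pass, which is what makes exact
ML on ~35,000 observations take about a second.

Estimation maximizes the likelihood over `(α, β, γ, log σ_ε)` with L-BFGS-B
(ftol 1e−12), starting from OLS for `(α, β)` and a within-donor lag
regression of OLS residuals for γ; candidates whose companion spectral
radius reaches 0.999 are rejected with a penalty so the line search
backtracks into the stationary region. Standard errors come from the inverse
central-difference Hessian at the optimum (delta method for σ²_ε). The
convergence flag reports the optimizer's own status.

**Linear mixed models.** Random intercept (RI):
`y = α + b_0i + β'x + ε`; random intercept and age slope (RIRS):
`y = α + b_0i + (β_age + b_1i)Age + β_s Season + β_d DPV + ε`, with
`(b_0i, b_1i) ~ N(0, D)`, D diagonal, independent of ε iid N(0, σ²_ε) —
conditional on the random effects a donor's residuals are independent.
Variance components are estimated by REML with fixed effects profiled out by
GLS. Each donor's contribution is reduced via the Woodbury identity to k×k
(k ≤ 2) cross-products, computed once per cohort, so a REML evaluation on
10,000 donors is a handful of batched matrix operations. Optimization is on
the log-variance scale (L-BFGS-B with central-difference gradients, bounded
to a wide window around var(y) for conditioning, followed by a Nelder–Mead
polish — the quasi-Newton step can stall on the flat log-scale direction of
a near-zero variance). A variance estimate below 1e−10 is reported as
exactly 0 with a boundary flag. Fixed-effect standard errors come from
`(X'V⁻¹X)⁻¹`; variance-component SEs from the log-scale Hessian by the delta
method. After the REML fit the model is re-maximized under ML (profile
likelihood in β, warm-started at the REML solution) and that ML value feeds
AIC/BIC, so information criteria are comparable across the OLS, transition
and mixed families. The RI intra-class correlation is
`ρ = σ²_b0/(σ²_b0+σ²_ε)`; it is refused for RIRS, where within-donor
correlation is not constant.

**Random-slope test.** `L = 2(ℓ_RIRS − ℓ_RI)` clipped at 0, referred to an
equal mixture of χ²(1) and χ²(2) — the null puts σ²_b1 on the boundary of
the parameter space. With a diagonal D a χ²(0)/χ²(1) mixture is also
defensible; the χ²(1)/χ²(2) mixture used here is the more conservative of
the two, so rejections are if anything understated.

## Dynamic prediction and evaluation

Predictions are causal: `ŷ_it` uses visits 1..t−1 only, never `y_it` itself.
For the transition model `ŷ_it = β'x_it + μ_w + E[z_it | z_i1..z_{i,t−1}]`
from the Kalman filter; for mixed models
`ŷ_it = x_it'β̂ + z_it'b̂_i`, with `b̂_i` the empirical-Bayes (BLUP) estimate
`D Z' V⁻¹ (y − Xβ̂)` computed on the prefix (prior mean 0 at t = 1, so first
visits are predicted from covariates alone in every model). The BLUP is
evaluated for all (donor, visit) pairs at once from exclusive cumulative
cross-products.

Evaluation uses a donor-level random split (each donor's whole series in
exactly one part). Deferral (observed Hb below the clinical cut-off,
8.4/7.8 mmol/l for men/women) is the positive class throughout; both
sensitivity and specificity are reported to avoid directional ambiguity. AUC
is the Mann–Whitney statistic with ties weighted 0.5 (scikit-learn), its SE
a stratified bootstrap over prediction entries. Two models are compared by a
*paired* bootstrap: the same entry indices, stratified by truth class, are
resampled for both models, and the observed AUC difference is referred to a
normal with the bootstrap SD. The entry-level bootstrap ignores within-donor
correlation of prediction errors, matching common ROC-comparison practice;
`p`-values should be read accordingly.

## Synthetic cohorts

The generator emulates a newly-registered whole-blood donor registry:
unbalanced panels (visit counts uniform on a configurable range, default
2–12), entry age uniform on 18–65, age incremented 0.20 years per visit
(roughly a 10-week median inter-visit interval), seasons iid Bernoulli(0.5)
(matching the ≈50% cold-season share of such registries while keeping the
generator date-free). Hb comes either from the transition process (latent
zero-mean AR(q), 50-step burn-in from a zero start — ample for |Σγ| well
inside 1) or from the mixed-model process. Donation status is *endogenous*:
`donated_t = 1{hb_t ≥ cutoff}` for t ≥ 2 (optionally thinned by a
non-Hb-deferral probability), `dpv_t = donated_{t−1}`, and visit 1 is never
a donation. Because the latent dynamics are independent of the covariate
path, the generated data satisfy the fitted conditional model exactly even
with this feedback — which the recovery tests confirm empirically
(estimates within 3 SE of generating values in ≥95% of replicates).

What the generator does **not** emulate: calendar spacing and the regulatory
donation caps (at most 5/3 donations per year, 8-week minimum interval),
measurement rounding, covariates beyond age/season/DPV (BMI, smoking,
nutrition), donor dropout correlated with deferral, and any non-Gaussian
features of real Hb. Passing recovery and ranking tests therefore shows the
estimators and the pipeline are correct under the stated processes, not that
the models capture everything in real donor data.

Default noise scales (the source estimates tables report none): transition
σ_ε = 0.5 mmol/l, chosen so the implied marginal Hb SD (≈0.58 at γ≈0.5)
matches typical adult within-gender Hb variability; mixed-model
(σ_b0, σ_b1, σ_ε) = (0.35, 0.005, 0.45), which reproduces realistic deferral
fractions (≈4% male, ≈19% female at the clinical cut-offs) and an ICC ≈ 0.4.

The reference intercepts in `donorhb.reference` are used exactly as
published. Under the as-printed transition parameterization the male AR(1)
column implies a stationary level `α/(1−γ₁) ≈ 19.9 mmol/l` — the published
intercept was evidently reported on the level scale — so cohorts simulated
from those columns sit far above the cut-off and contain no deferrals. This
is harmless for parameter recovery (generator and estimator share the
parameterization) but examples that need realistic deferral rates rescale α
to `level × (1−Σγ)` explicitly.

## Numerical choices and edge cases

* Stationarity guard at spectral radius 0.999; violations during fitting are
  penalized, violations in user-supplied parameters raise with the offending
  root modulus.
* Boundary variances reported as exact zeros with a flag (tolerance 1e−10).
* Ties in predicted scores: 0.5 weight in AUC; ROC points from the distinct
  observed scores.
* Degenerate classification inputs (single truth class) yield `None` rates
  and skip the ROC block rather than reporting 0.
* Donors with missing Hb are excluded at read time behind an explicit flag;
  fitting functions require structurally valid cohorts (`validate_panel`
  returns violations as data for triage, it never raises).
* All randomness is seeded per stage (generator, split, bootstraps); rerunning
  an experiment config reproduces outputs byte-for-byte.

## Problem sizes

Recovery experiments use 5,000 donors (8,000 for the male RI target) with
2–12 visits, the replicate-based checks 100–240 donors per replicate across
60–100 replicates; these sizes give sampling error comfortably inside the
3-SE acceptance bands while keeping a full test run in a few minutes.
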