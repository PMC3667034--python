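# donorhb

Dynamic hemoglobin (Hb) prediction for whole-blood donors: transition
(autoregressive panel) models versus linear mixed effects models.

## The problem

Blood banks defer a donor at a visit when the fingerstick Hb falls below the
clinical cut-off — 8.4 mmol/l for men, 7.8 mmol/l for women. Deferral wastes a
visit and demotivates volunteers, so banks want to *predict* the next Hb value
from a donor's history and invite only donors likely to be eligible. The data
are unbalanced longitudinal panels: per donor a sequence of visits with Hb,
age, season (warm/cold) and DPV, a binary flag for a donation at the previous
visit (a donor's first visit is a health check, so DPV there is 0 by
definition). Analyses are run per gender.

`donorhb` implements and compares, on synthetic cohorts with this exact
structure, the three model families used for this task:

* **Pooled linear regression (benchmark)**
  `y_it = α + β₁Age_it + β₂Season_it + β₃DPV_it + ε_it` — ignores within-donor
  correlation by design.
* **Transition model of order q**
  `y_it = α + β'x_it + Σ_r γ_r (y_{i,t−r} − β'x_{i,t−r}) + ε_it` — the
  covariate-adjusted series w = y − β'x is a stationary AR(q). The likelihood
  is evaluated *exactly* via a companion-form Kalman filter started from the
  stationary distribution, so donors with fewer visits than the model order
  still contribute through the stationary marginal.
* **Linear mixed models**, random intercept (RI) or random intercept plus
  random age slope (RIRS, diagonal random-effects covariance), fitted by REML
  with fixed effects profiled out by GLS. The RI intra-class correlation is
  ρ = σ²_b0/(σ²_b0+σ²_ε); the random slope is tested with the boundary
  likelihood-ratio test referred to an equal χ²(1)/χ²(2) mixture.

Prediction is *dynamic*: visit t is predicted from visits 1..t−1 only — the
Kalman one-step-ahead state for the transition model, empirical-Bayes (BLUP)
random effects for the mixed model. Accuracy is assessed by visit-wise mean
squared prediction error `MSPE_t = Σ_i (ŷ_it − y_it)²/N_t` on a donor-level
validation split, AIC/BIC on the training fit, deferral
sensitivity/specificity at the clinical cut-off, ROC/AUC, and a paired
bootstrap test for AUC differences between models.

Because real donor registries are not redistributable, the package ships a
synthetic cohort generator that emulates the panel structure, including the
feedback loop that makes DPV endogenous: a donor donates at visit t ≥ 2
exactly when the generated Hb clears the cut-off. Published per-gender
regression estimates from a large Dutch donor registry
(`donorhb.reference`) serve as generating truth for recovery experiments.

## Worked example

```python
from donorhb import CohortConfig, fit_transition, simulate_transition_cohort
from donorhb import reference as ref

cohort = simulate_transition_cohort(
    ref.MALE_AR1, CohortConfig(n_donors=2000, gender="M", seed=7)
)
fit = fit_transition(cohort, q=1)
print(fit.params.gamma[0], fit.se["gamma_1"])
```

Running `python examples/02_fit_transition_model.py` (which wraps the above)
prints:

```
converged: True   loglik: -10769.5
parameter     estimate       SE     truth
alpha           9.5733   0.1480    9.6309
beta_age       -0.0048   0.0006   -0.0043
beta_season    -0.0655   0.0077   -0.0615
beta_dpv       -0.0391   0.0116   -0.0469
gamma_1         0.5190   0.0074    0.5158
sigma2_eps      0.2558   0.0031    0.2500
```

Each estimate sits within a few standard errors of the generating value;
`gamma_1 ≈ 0.52` says half of a donor's covariate-adjusted Hb deviation
carries over to the next visit. `examples/04_compare_models.py` runs the
full comparison on one synthetic cohort and prints the model-ranking table
(transition model best on AIC, MSPE and AUC; both dynamic models far ahead
of the pooled regression), e.g.

```
model          AIC       BIC    MSPE   sens   spec    AUC
LR         11816.0   11850.3   0.307   0.00   1.00  0.629
LME-RI     11399.6   11440.8   0.290   0.07   0.98  0.661
AR(1)      10553.2   10594.3   0.256   0.19   0.96  0.726
```

The other examples cover cohort simulation, the mixed-model/LRT workflow and
the end-to-end experiment runner. The same pipeline is scriptable from the
shell:

```sh
donorhb run --config experiment.yaml --outdir out
```

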