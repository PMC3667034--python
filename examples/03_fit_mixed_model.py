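"""REML mixed-model fit, intra-class correlation and the random-slope test.

Simulates a female cohort from the random-intercept+slope process, fits both
random-effect structures, and runs the boundary-mixture likelihood-ratio
test for the random age slope.
"""

from donorhb import CohortConfig, fit_lme, icc, lrt_random_slope, simulate_lme_cohort
from donorhb import reference as ref

config = CohortConfig(n_donors=1500, gender="F", seed=13)
cohort = simulate_lme_cohort(ref.FEMALE_LME_RIRS, config)

ri = fit_lme(cohort, structure="RI")
rirs = fit_lme(cohort, structure="RIRS")

print("random intercept fit:")
print(f"  beta_dpv = {ri.params.beta[2]:.4f} (SE {ri.se['beta_dpv']:.4f})")
print(f"  sigma2_b0 = {ri.params.sigma2_b0:.4f}, sigma2_eps = {ri.params.sigma2_eps:.4f}")
print(f"  intra-class correlation = {icc(ri.params):.3f}")
print("random intercept + age slope fit:")
print(f"  sigma2_b1 = {rirs.params.sigma2_b1:.2e} (truth {ref.SIGMA_B1**2:.2e})")

L, p = lrt_random_slope(ri, rirs)
print(f"mixture chi2(1,2) LRT: L = {L:.2f}, p = {p:.4g}")
# A small p-value says donor-specific age trends improve the fit beyond a
# shared age effect, as expected since the generator included a random slope.
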