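"""Reference parameter sets for realistic donor-cohort simulations.

These are published regression estimates (with standard errors) from a large
Dutch whole-blood donor registry analysis of Hb dynamics, fitted separately
for men and women.  They serve as generating truth for parameter-recovery
experiments and as defaults for realistic synthetic cohorts.  The source
analysis did not report residual or random-effect variances, so the variance
settings used in simulations are package defaults, not published values:
sigma_eps = 0.5 mmol/l for the transition process and
(sigma_b0, sigma_b1, sigma_eps) = (0.35, 0.005, 0.45) for the mixed-model
process.

The covariate coefficient order is (age per-year, warm-season, DPV),
all in mmol/l.
"""

from __future__ import annotations

from .mixed import LMEParams
from .transition import TransitionParams

__all__ = [
    "MALE_AR1", "MALE_AR2", "FEMALE_AR1",
    "MALE_LME_RI", "FEMALE_LME_RIRS",
    "MALE_LR", "FEMALE_LR",
    "SE_MALE_AR1", "SE_MALE_AR2", "SE_FEMALE_AR1",
    "SE_MALE_LME", "SE_FEMALE_LME",
    "SIGMA_EPS_AR", "SIGMA_B0", "SIGMA_B1", "SIGMA_EPS_LME",
]

# default simulation noise scales (standard deviations, mmol/l)
SIGMA_EPS_AR = 0.5
SIGMA_B0 = 0.35
SIGMA_B1 = 0.005
SIGMA_EPS_LME = 0.45

MALE_AR1 = TransitionParams(
    alpha=9.6309, beta=(-0.0043, -0.0615, -0.0469),
    gamma=(0.5158,), sigma2_eps=SIGMA_EPS_AR**2,
)
SE_MALE_AR1 = {"alpha": 0.0206, "beta_age": 0.0005, "beta_season": 0.0074,
               "beta_dpv": 0.0089, "gamma_1": 0.0061}

MALE_AR2 = TransitionParams(
    alpha=9.6441, beta=(-0.0044, -0.0681, -0.0350),
    gamma=(0.3685, 0.2888), sigma2_eps=SIGMA_EPS_AR**2,
)
SE_MALE_AR2 = {"alpha": 0.0231, "beta_age": 0.0006, "beta_season": 0.0066,
               "beta_dpv": 0.0079, "gamma_1": 0.0068, "gamma_2": 0.0078}

FEMALE_AR1 = TransitionParams(
    alpha=8.2394, beta=(0.0044, -0.0405, -0.1411),
    gamma=(0.4669,), sigma2_eps=SIGMA_EPS_AR**2,
)
SE_FEMALE_AR1 = {"alpha": 0.0164, "beta_age": 0.0004, "beta_season": 0.0062,
                 "beta_dpv": 0.0075, "gamma_1": 0.0062}

MALE_LME_RI = LMEParams(
    alpha=9.6719, beta=(-0.0049, -0.0698, -0.0636),
    sigma2_b0=SIGMA_B0**2, sigma2_b1=None, sigma2_eps=SIGMA_EPS_LME**2,
    structure="RI",
)
SE_MALE_LME = {"alpha": 0.0243, "beta_age": 0.0006, "beta_season": 0.0067,
               "beta_dpv": 0.0068}

FEMALE_LME_RIRS = LMEParams(
    alpha=8.2832, beta=(0.0037, -0.0411, -0.1387),
    sigma2_b0=SIGMA_B0**2, sigma2_b1=SIGMA_B1**2, sigma2_eps=SIGMA_EPS_LME**2,
    structure="RIRS",
)
SE_FEMALE_LME = {"alpha": 0.0181, "beta_age": 0.0005, "beta_season": 0.0062,
                 "beta_dpv": 0.0060}

MALE_LR = LMEParams(
    alpha=9.6448, beta=(-0.0045, -0.0627, -0.0610),
    sigma2_b0=0.0, sigma2_b1=None, sigma2_eps=SIGMA_EPS_LME**2, structure="LR",
)

FEMALE_LR = LMEParams(
    alpha=8.2737, beta=(0.0042, -0.0347, -0.1106),
    sigma2_b0=0.0, sigma2_b1=None, sigma2_eps=SIGMA_EPS_LME**2, structure="LR",
)
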