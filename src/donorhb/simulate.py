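"""Synthetic donor-cohort generators.

Both generators build unbalanced visit panels with the covariate structure of
a whole-blood donor registry: per-visit age (entry age plus a fixed increment
per visit), an iid warm-season indicator, and DPV (donation at the previous
visit) fed back *endogenously* — a donor donates at visit t >= 2 exactly when
the generated Hb clears the clinical cut-off for their gender (and, if
enabled, survives a non-Hb deferral coin flip).  A donor's first visit is a
health check, never a donation, so DPV at visit 1 is always 0.

Hb itself comes from one of the two data-generating processes the package
fits:

* :func:`simulate_transition_cohort` — a latent zero-mean AR(q) plus the
  covariate effects and the stationary mean mu_w = alpha / (1 - sum gamma).
* :func:`simulate_lme_cohort` — donor-specific random intercept (and
  optionally random age slope) plus iid Gaussian noise.

Because the latent dynamics never depend on the covariates, the generated
data satisfy the fitted model's conditional specification exactly even with
the donation feedback in place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixed import LMEParams
from .panel import COLUMNS, Cohort, EligibilityRule, Gender
from .transition import TransitionParams, _check_stationary

__all__ = ["CohortConfig", "simulate_transition_cohort", "simulate_lme_cohort"]

#: AR burn-in length before the kept series starts
_BURN_IN = 50


@dataclass(frozen=True)
class CohortConfig:
    """Shape and covariate settings of a simulated cohort.

    ``age_increment`` defaults to 0.20 years per visit, roughly the median
    male inter-visit interval of about 10 weeks.  ``p_other_deferral`` is the
    probability that a donor whose Hb clears the cut-off is nevertheless
    deferred for another reason (0 disables the mechanism, which keeps the
    DPV chain a deterministic function of past Hb).
    """

    n_donors: int
    gender: Gender
    seed: int
    visits_min: int = 2
    visits_max: int = 12
    age_entry_low: float = 18.0
    age_entry_high: float = 65.0
    age_increment: float = 0.20
    p_warm: float = 0.5
    p_other_deferral: float = 0.0

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ValueError("n_donors must be positive")
        if self.visits_min < 2 or self.visits_max < self.visits_min:
            raise ValueError("need visits_max >= visits_min >= 2")
        if not 0.0 <= self.p_warm <= 1.0:
            raise ValueError("p_warm must lie in [0, 1]")
        if not 0.0 <= self.p_other_deferral < 1.0:
            raise ValueError("p_other_deferral must lie in [0, 1)")
        if self.age_increment <= 0:
            raise ValueError("age_increment must be positive")
        object.__setattr__(self, "gender", Gender(self.gender))


def _panel_skeleton(config: CohortConfig, rng: np.random.Generator):
    """Visit counts, ages and seasons for every donor; shared by both processes."""
    n = config.n_donors
    T = rng.integers(config.visits_min, config.visits_max + 1, size=n)
    t_max = int(T.max())
    entry_age = rng.uniform(config.age_entry_low, config.age_entry_high, size=n)
    ages = entry_age[:, None] + config.age_increment * np.arange(t_max)[None, :]
    seasons = (rng.random((n, t_max)) < config.p_warm).astype(int)
    return T, t_max, ages, seasons


def _assemble(
    config: CohortConfig,
    T: np.ndarray,
    ages: np.ndarray,
    seasons: np.ndarray,
    dpv: np.ndarray,
    donated: np.ndarray,
    hb: np.ndarray,
) -> Cohort:
    n, t_max = ages.shape
    width = len(str(n))
    ids = np.array([f"d{j:0{width}d}" for j in range(n)])
    mask = np.arange(t_max)[None, :] < T[:, None]
    rows = {
        "donor_id": np.repeat(ids, T),
        "gender": config.gender.value,
        "visit": (np.tile(np.arange(1, t_max + 1), (n, 1)))[mask],
        "age": ages[mask],
        "season": seasons[mask],
        "dpv": dpv[mask],
        "donated": donated[mask],
        "hb": hb[mask],
    }
    return Cohort(pd.DataFrame(rows, columns=COLUMNS), config.gender)


def _donation_feedback(
    hb_base: "np.ndarray",
    beta_dpv: float,
    cutoff: float,
    p_other: float,
    T: np.ndarray,
    rng: np.random.Generator,
):
    """Run the sequential DPV chain.

    ``hb_base`` is the Hb that each visit would show with DPV = 0; adding
    ``beta_dpv`` when DPV = 1 gives the realized Hb.  Returns (hb, dpv,
    donated) matrices.
    """
    n, t_max = hb_base.shape
    hb = np.empty_like(hb_base)
    dpv = np.zeros((n, t_max), dtype=int)
    donated = np.zeros((n, t_max), dtype=int)
    other_ok = (
        rng.random((n, t_max)) >= p_other if p_other > 0 else np.ones((n, t_max), bool)
    )
    for t in range(t_max):
        if t > 0:
            dpv[:, t] = donated[:, t - 1]
        hb[:, t] = hb_base[:, t] + beta_dpv * dpv[:, t]
        if t > 0:  # the first visit is a health check, never a donation
            donated[:, t] = (hb[:, t] >= cutoff) & other_ok[:, t]
    return hb, dpv, donated


def simulate_transition_cohort(
    params: TransitionParams,
    config: CohortConfig,
    rule: EligibilityRule = EligibilityRule(),
) -> Cohort:
    """Simulate a cohort whose Hb follows the order-q transition process.

    Each donor carries an independent latent zero-mean AR(q) series z_t
    (innovation variance sigma2_eps), started from zeros and burned in for 50
    steps; the observed Hb is mu_w + z_t + beta'(age, season, dpv) with
    donation status fed back through the clinical cut-off.
    """
    _check_stationary(params.gamma)  # TransitionParams enforces this; belt and braces
    rng = np.random.default_rng(config.seed)
    T, t_max, ages, seasons = _panel_skeleton(config, rng)
    n = config.n_donors
    q = params.q
    gamma = np.asarray(params.gamma)

    steps = _BURN_IN + t_max
    eps = rng.normal(0.0, np.sqrt(params.sigma2_eps), size=(n, steps))
    z = np.zeros((n, steps + q))
    for t in range(steps):
        z[:, q + t] = z[:, t : q + t][:, ::-1] @ gamma + eps[:, t] if q else eps[:, t]
    z = z[:, q + _BURN_IN :]

    b_age, b_season, b_dpv = params.beta
    hb_base = params.stationary_mean + z + b_age * ages + b_season * seasons
    cutoff = rule.cutoff(config.gender)
    hb, dpv, donated = _donation_feedback(
        hb_base, b_dpv, cutoff, config.p_other_deferral, T, rng
    )
    return _assemble(config, T, ages, seasons, dpv, donated, hb)


def simulate_lme_cohort(
    params: LMEParams,
    config: CohortConfig,
    rule: EligibilityRule = EligibilityRule(),
) -> Cohort:
    """Simulate a cohort whose Hb follows the mixed-model process.

    Per donor, b0 ~ N(0, sigma2_b0) and (for the RIRS structure)
    b1 ~ N(0, sigma2_b1) independently; Hb at visit t is
    alpha + b0 + (beta_age + b1) age_t + beta_season season_t
    + beta_dpv dpv_t + eps_t with iid N(0, sigma2_eps) noise and the same
    donation feedback as the transition generator.
    """
    rng = np.random.default_rng(config.seed)
    T, t_max, ages, seasons = _panel_skeleton(config, rng)
    n = config.n_donors
    b0 = rng.normal(0.0, np.sqrt(params.sigma2_b0), size=n)
    s2b1 = params.sigma2_b1 if params.structure == "RIRS" else 0.0
    b1 = rng.normal(0.0, np.sqrt(s2b1), size=n) if s2b1 else np.zeros(n)
    eps = rng.normal(0.0, np.sqrt(params.sigma2_eps), size=(n, t_max))

    b_age, b_season, b_dpv = params.beta
    hb_base = (
        params.alpha
        + b0[:, None]
        + (b_age + b1[:, None]) * ages
        + b_season * seasons
        + eps
    )
    cutoff = rule.cutoff(config.gender)
    hb, dpv, donated = _donation_feedback(
        hb_base, b_dpv, cutoff, config.p_other_deferral, T, rng
    )
    return _assemble(config, T, ages, seasons, dpv, donated, hb)
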