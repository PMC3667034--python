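import pandas as pd
import pytest

from donorhb import (
    Cohort,
    CohortConfig,
    Gender,
    simulate_lme_cohort,
    simulate_transition_cohort,
)
from donorhb import reference as ref
from donorhb.panel import COLUMNS


def build_cohort(rows, gender="M"):
    """Assemble a Cohort from (donor_id, visit, age, season, dpv, donated, hb) tuples."""
    df = pd.DataFrame(
        rows, columns=["donor_id", "visit", "age", "season", "dpv", "donated", "hb"]
    )
    df["gender"] = Gender(gender).value
    return Cohort(df[COLUMNS], gender)


def random_valid_cohort(rng, n_donors=6, t_max=8, gender="M"):
    """A structurally valid cohort with arbitrary (iid) Hb values."""
    rows = []
    for d in range(n_donors):
        T = int(rng.integers(2, t_max + 1))
        donated_prev = 0
        age = float(rng.uniform(18, 65))
        for t in range(1, T + 1):
            donated = int(rng.integers(0, 2)) if t >= 2 else 0
            rows.append(
                (
                    f"d{d:03d}", t, age + 0.2 * (t - 1),
                    int(rng.integers(0, 2)), donated_prev, donated,
                    float(rng.normal(9.5, 0.6)),
                )
            )
            donated_prev = donated
    return build_cohort(rows, gender)


@pytest.fixture(scope="session")
def ar_small():
    cfg = CohortConfig(n_donors=250, gender="M", seed=71)
    return simulate_transition_cohort(ref.MALE_AR1, cfg)


@pytest.fixture(scope="session")
def lme_small():
    cfg = CohortConfig(n_donors=250, gender="M", seed=72)
    return simulate_lme_cohort(ref.MALE_LME_RI, cfg)


@pytest.fixture(scope="session")
def lme_small_female():
    cfg = CohortConfig(n_donors=250, gender="F", seed=73)
    return simulate_lme_cohort(ref.FEMALE_LME_RIRS, cfg)
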