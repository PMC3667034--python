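"""Donor panel data structures, long-format CSV I/O, validation and splitting.

A *cohort* is an unbalanced panel of hemoglobin (Hb) measurements: each donor
contributes a series of visits, indexed by the sequential visit number
(calendar time is deliberately not modelled).  Every visit carries the
covariates used by the prediction models — age in years, a binary warm-season
indicator, and DPV, the indicator of a donation at the *previous* visit — plus
the donation outcome of the visit itself and the measured Hb in mmol/l.

Analyses are run per gender; the clinical eligibility cut-offs are
8.4 mmol/l for men and 7.8 mmol/l for women.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "Gender",
    "VisitRecord",
    "Cohort",
    "EligibilityRule",
    "PanelFormatError",
    "Violation",
    "read_panel",
    "write_panel",
    "validate_panel",
    "split_donors",
]

#: canonical long-format column order
COLUMNS = ["donor_id", "gender", "visit", "age", "season", "dpv", "donated", "hb"]


class Gender(str, Enum):
    male = "M"
    female = "F"


class PanelFormatError(ValueError):
    """Raised when a panel file violates the declared CSV contract."""


@dataclass(frozen=True)
class VisitRecord:
    """One Hb measurement with covariates at one visit of one donor."""

    donor_id: str
    gender: Gender
    visit: int          # 1-based sequential visit number
    age: float          # years
    season: int         # 0 = cold (fall/winter), 1 = warm (spring/summer)
    dpv: int            # donation at previous visit (0 at visit 1 by definition)
    donated: int        # donation made at THIS visit
    hb: float           # mmol/l


@dataclass(frozen=True)
class EligibilityRule:
    """Clinical Hb cut-offs for donation eligibility (mmol/l)."""

    cutoff_male: float = 8.4
    cutoff_female: float = 7.8

    def __post_init__(self) -> None:
        if not (self.cutoff_male > self.cutoff_female > 0):
            raise ValueError(
                "expected cutoff_male > cutoff_female > 0, got "
                f"{self.cutoff_male!r} / {self.cutoff_female!r}"
            )

    def cutoff(self, gender: Gender) -> float:
        return self.cutoff_male if Gender(gender) is Gender.male else self.cutoff_female


@dataclass
class Cohort:
    """A per-gender collection of donor visit series, stored long-format.

    The backing :class:`pandas.DataFrame` uses the canonical columns and is
    kept sorted by ``(donor_id, visit)``.
    """

    data: pd.DataFrame
    gender: Gender

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise PanelFormatError(f"cohort frame missing column(s): {missing}")
        self.data = (
            self.data.loc[:, COLUMNS]
            .sort_values(["donor_id", "visit"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.gender = Gender(self.gender)

    # -- convenience accessors -------------------------------------------------
    @property
    def n_donors(self) -> int:
        return self.data["donor_id"].nunique()

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def donor_ids(self) -> np.ndarray:
        return self.data["donor_id"].unique()

    def groupby_donor(self):
        return self.data.groupby("donor_id", sort=True)

    def iter_series(self) -> Iterable[tuple[str, pd.DataFrame]]:
        yield from self.groupby_donor()

    def records(self) -> list[VisitRecord]:
        return [
            VisitRecord(
                donor_id=str(r.donor_id), gender=self.gender, visit=int(r.visit),
                age=float(r.age), season=int(r.season), dpv=int(r.dpv),
                donated=int(r.donated), hb=float(r.hb),
            )
            for r in self.data.itertuples(index=False)
        ]


@dataclass(frozen=True)
class Violation:
    """One structural-invariant violation found by :func:`validate_panel`."""

    donor_id: str
    visit: Optional[int]
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f"visit {self.visit}" if self.visit is not None else "series"
        return f"donor {self.donor_id}, {loc}: {self.rule}"


_DTYPES = {
    "visit": int, "season": int, "dpv": int, "donated": int,
    "age": float, "hb": float,
}


def read_panel(
    path: Union[str, Path],
    gender_filter: Optional[Union[str, Gender]] = None,
    drop_missing_hb: bool = False,
) -> Cohort:
    """Read a long-format donor panel CSV into a :class:`Cohort`.

    Parameters
    ----------
    path
        CSV file with header row and columns ``donor_id, gender, visit, age,
        season, dpv, donated, hb`` (comma-separated, '.' decimal).
    gender_filter
        Keep only rows of this gender ("M"/"F").  Required when the file mixes
        genders, since a Cohort is single-gender.
    drop_missing_hb
        When True, donors with a missing Hb at *any* visit are excluded
        entirely (mirrors the exclusion applied to the source registry);
        when False a missing Hb is a parse error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype={"donor_id": str, "gender": str})
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise PanelFormatError(
            f"panel file {path.name} lacks required column(s): {', '.join(missing)}"
        )
    raw = raw.loc[:, COLUMNS]

    if gender_filter is not None:
        raw = raw[raw["gender"] == Gender(gender_filter).value]
    genders = raw["gender"].unique()
    if len(genders) > 1:
        raise PanelFormatError(
            f"panel mixes genders {sorted(genders)}; pass gender_filter to select one"
        )
    if len(genders) == 0:
        raise PanelFormatError("no rows after gender filtering")

    hb = pd.to_numeric(raw["hb"], errors="coerce")
    bad_hb = hb.isna()
    if bad_hb.any():
        if drop_missing_hb:
            bad_donors = raw.loc[bad_hb, "donor_id"].unique()
            raw = raw[~raw["donor_id"].isin(bad_donors)]
            hb = pd.to_numeric(raw["hb"])
        else:
            row = int(raw.index[bad_hb][0]) + 2  # 1-based, + header
            raise PanelFormatError(f"non-numeric hb value at file row {row}")
    raw = raw.assign(hb=hb).astype(_DTYPES)
    return Cohort(raw, Gender(genders[0]))


def write_panel(cohort: Cohort, path: Union[str, Path]) -> None:
    """Write a cohort to CSV in the canonical column order (UTF-8, '.' decimal)."""
    if cohort.n_obs == 0:
        raise ValueError("refusing to write an empty cohort")
    cohort.data.to_csv(path, index=False, encoding="utf-8")


def validate_panel(cohort: Cohort) -> list[Violation]:
    """Check the structural invariants of a donor panel.

    Violations are returned as data (not raised) so that messy real-world
    panels can be triaged; model-fitting functions require a clean cohort.

    Checks, per donor: visits are consecutive integers starting at 1; DPV at
    visit 1 is 0 (a donor's first visit is a health check, not a donation);
    DPV at visit t equals the donation flag at visit t−1; age is
    non-decreasing; Hb is positive; the series has at least 2 visits.
    """
    out: list[Violation] = []
    for donor_id, g in cohort.groupby_donor():
        visits = g["visit"].to_numpy()
        if len(g) < 2:
            out.append(Violation(donor_id, None, "donor has fewer than 2 visits"))
        if not np.array_equal(visits, np.arange(1, len(g) + 1)):
            out.append(Violation(donor_id, None, "non-consecutive visit numbers"))
            continue  # remaining checks assume an ordered series
        dpv = g["dpv"].to_numpy()
        donated = g["donated"].to_numpy()
        if dpv[0] != 0:
            out.append(Violation(donor_id, 1, "DPV at first visit must be 0"))
        mism = np.nonzero(dpv[1:] != donated[:-1])[0]
        for j in mism:
            out.append(
                Violation(donor_id, int(visits[j + 1]),
                          "DPV does not equal donation flag of previous visit")
            )
        age = g["age"].to_numpy()
        if np.any(np.diff(age) < 0):
            out.append(Violation(donor_id, None, "age decreases within series"))
        for j in np.nonzero(g["hb"].to_numpy() <= 0)[0]:
            out.append(Violation(donor_id, int(visits[j]), "hb must be positive"))
    return out


def split_donors(cohort: Cohort, fraction: float, seed: int) -> tuple[Cohort, Cohort]:
    """Randomly split a cohort at the *donor* level.

    Each donor's full visit series lands in exactly one part: the first part
    receives ``round(fraction * n_donors)`` donors drawn as a simple random
    sample of donor ids, the second the remainder.  Reproducible given seed.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    ids = np.sort(cohort.donor_ids())
    rng = np.random.default_rng(seed)
    n_first = int(round(fraction * len(ids)))
    n_first = min(max(n_first, 1), len(ids) - 1)
    chosen = rng.choice(ids, size=n_first, replace=False)
    mask = cohort.data["donor_id"].isin(set(chosen))
    part_a = Cohort(cohort.data[mask].copy(), cohort.gender)
    part_b = Cohort(cohort.data[~mask].copy(), cohort.gender)
    return part_a, part_b
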