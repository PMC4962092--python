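"""Reference-population life tables on a monthly hazard scale.

The lifetime extrapolation used throughout this package is a relative-survival
construction: the study cohort's survival is compared with the expected
survival of an age- and sex-matched slice of the general population.  That
reference mortality is carried here as a table of *monthly* hazards indexed by
integer age (0-110 years) and sex, the same bookkeeping unit as the rest of
the pipeline.

A parametric builder is provided for synthetic work: Gompertz mortality,
``h(age) = a * exp(b * age)`` per month, which is the standard two-parameter
description of adult human mortality and gives the generator and the
estimators a shared, analytically tractable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MAX_AGE = 110
SEXES = ("M", "F")

__all__ = ["GompertzParams", "LifeTable", "build_life_table"]


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz monthly-hazard parameters ``h(age) = a * exp(b * age)``.

    ``a`` is the monthly baseline hazard at age 0 (dimensionless, >= 0) and
    ``b`` the log-hazard slope per year of age (>= 0).
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError(f"Gompertz baseline hazard must be >= 0, got a={self.a}")
        if self.b < 0:
            raise ValueError(f"Gompertz shape must be >= 0, got b={self.b}")


class LifeTable:
    """Age x sex grid of monthly background mortality hazards.

    Parameters
    ----------
    table:
        DataFrame with columns ``age`` (integer years), ``sex`` (``"M"``/``"F"``)
        and ``hazard`` (monthly hazard, >= 0).  Every (age, sex) combination
        for ages 0..110 must appear exactly once.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"age", "sex", "hazard"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"life table missing columns: {sorted(missing)}")
        if (table["hazard"] < 0).any():
            raise ValueError("life-table hazards must be >= 0")
        self._hazards: dict[str, np.ndarray] = {}
        for sex in SEXES:
            sub = table.loc[table["sex"] == sex].sort_values("age")
            ages = sub["age"].to_numpy()
            if not np.array_equal(ages, np.arange(MAX_AGE + 1)):
                raise ValueError(
                    f"life table for sex={sex!r} must cover ages 0..{MAX_AGE} exactly once"
                )
            self._hazards[sex] = sub["hazard"].to_numpy(dtype=float)
        self.table = table.reset_index(drop=True)

    def hazard(self, age: int, sex: str) -> float:
        """Monthly hazard at integer ``age``; ages beyond the table carry the final value."""
        return float(self._hazards[sex][min(int(age), MAX_AGE)])

    def hazard_paths(self, ages: np.ndarray, sexes: np.ndarray, n_months: int) -> np.ndarray:
        """Monthly hazard trajectories for subjects aging through the table.

        Ages advance in months; the hazard applied in month ``u`` (0-based) is
        the table value at the attained integer age ``floor(age + u/12)``.
        Beyond age 110 the final hazard is carried forward.

        Returns an ``(n_subjects, n_months)`` array.
        """
        ages = np.asarray(ages, dtype=float)
        sexes = np.asarray(sexes)
        if (ages < 0).any() or (ages > MAX_AGE).any():
            raise ValueError("subject age outside the life table's range 0..110")
        months = np.arange(n_months)
        attained = np.floor(ages[:, None] + months[None, :] / 12.0).astype(int)
        attained = np.minimum(attained, MAX_AGE)
        out = np.empty((len(ages), n_months), dtype=float)
        for sex in SEXES:
            mask = sexes == sex
            if mask.any():
                out[mask] = self._hazards[sex][attained[mask]]
        return out

    def survival_path(self, age: float, sex: str, n_months: int) -> np.ndarray:
        """Expected survival exp(-cumulative hazard) on months 0..n_months."""
        h = self.hazard_paths(np.array([age]), np.array([sex]), n_months)[0]
        return np.exp(-np.concatenate([[0.0], np.cumsum(h)]))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path))


def build_life_table(params: dict[str, GompertzParams]) -> LifeTable:
    """Tabulate Gompertz monthly hazards for ages 0..110, one row per (age, sex).

    ``params`` maps each sex to its :class:`GompertzParams`.  A baseline of
    ``a=0`` yields an all-zero hazard table (survival identically 1), which is
    a supported degenerate case for testing.
    """
    for sex in SEXES:
        if sex not in params:
            raise ValueError(f"missing Gompertz parameters for sex {sex!r}")
    rows = []
    ages = np.arange(MAX_AGE + 1)
    for sex in SEXES:
        p = params[sex]
        rows.append(
            pd.DataFrame({"age": ages, "sex": sex, "hazard": p.a * np.exp(p.b * ages)})
        )
    return LifeTable(pd.concat(rows, ignore_index=True))
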