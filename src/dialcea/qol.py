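"""EQ-5D utility scoring and the kernel-smoothed utility-by-vintage curve.

The EQ-5D-3L instrument describes a health state as five domain levels
(mobility, self-care, usual activities, pain/discomfort, anxiety/depression),
each 1 (no problems) to 3 (extreme problems).  A country-specific *value set*
(tariff) maps each of the 243 profiles to a utility anchored at 1 (full
health) and 0 (death); several published tariffs extend below 0 for states
considered worse than death.  Value sets are data, not code: this package
ships a UK-style additive time-trade-off tariff as a YAML coefficient table
and accepts any table with the same schema (a Taiwanese tariff is not
published in coefficient form, so a documented template slot is provided
instead of invented numbers).

Scoring is additive::

    u = 1 - c_any * I(any level > 1) - sum(level decrements) - c_extreme * I(any level = 3)

The mean quality-of-life trajectory over dialysis vintage is estimated by a
nearest-neighbour kernel smoother: at each grid month the mean of the k
nearest observations by vintage, with k the larger of 10% of the sample and
50 records (the sampling floor below which the smoother refuses to run).
Beyond the last observed vintage the curve is carried forward flat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from itertools import product

import numpy as np
import pandas as pd
import yaml

DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

MIN_SMOOTHING_N = 50

__all__ = [
    "DIMENSIONS",
    "ValueSet",
    "UtilityCurve",
    "load_value_set",
    "uk_tariff",
    "score_eq5d",
    "profile_scores",
    "utility_to_profile",
    "smooth_utility",
    "extend_utility",
]


@dataclass(frozen=True)
class ValueSet:
    """Additive EQ-5D-3L tariff.

    ``decrements[dim][level]`` holds the utility loss for ``level`` in {2, 3}
    of dimension ``dim``; ``any_dysfunction_constant`` is subtracted once if
    any level exceeds 1, ``extreme_level_constant`` once if any level is 3.
    """

    name: str
    any_dysfunction_constant: float
    extreme_level_constant: float
    decrements: dict[str, dict[int, float]]

    def __post_init__(self) -> None:
        if self.any_dysfunction_constant < 0 or self.extreme_level_constant < 0:
            raise ValueError("tariff constants must be >= 0")
        for dim in DIMENSIONS:
            if dim not in self.decrements:
                raise ValueError(f"value set {self.name!r} missing dimension {dim!r}")
            for lvl in (2, 3):
                if self.decrements[dim].get(lvl, -1.0) < 0:
                    raise ValueError(f"decrement for {dim!r} level {lvl} must be >= 0")

    @property
    def min_value(self) -> float:
        """Utility of the worst state (3,3,3,3,3); the tariff's floor."""
        return self.score((3, 3, 3, 3, 3))

    def score(self, levels) -> float:
        return score_eq5d(levels, self)


def score_eq5d(levels, value_set: ValueSet) -> float:
    """Score a five-level EQ-5D-3L profile under an additive tariff."""
    levels = tuple(int(v) for v in levels)
    if len(levels) != 5:
        raise ValueError(f"expected 5 domain levels, got {len(levels)}")
    if any(lvl not in (1, 2, 3) for lvl in levels):
        raise ValueError(f"EQ-5D levels must be in {{1,2,3}}, got {levels}")
    u = 1.0
    if any(lvl > 1 for lvl in levels):
        u -= value_set.any_dysfunction_constant
    for dim, lvl in zip(DIMENSIONS, levels):
        if lvl > 1:
            u -= value_set.decrements[dim][lvl]
    if any(lvl == 3 for lvl in levels):
        u -= value_set.extreme_level_constant
    return u


def load_value_set(path) -> ValueSet:
    """Read a tariff from a YAML coefficient table (see data/value_set_template.yaml)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    decs = {
        dim: {int(lvl): float(v) for lvl, v in table.items()}
        for dim, table in raw["decrements"].items()
    }
    return ValueSet(
        name=raw["name"],
        any_dysfunction_constant=float(raw["any_dysfunction_constant"]),
        extreme_level_constant=float(raw["extreme_level_constant"]),
        decrements=decs,
    )


def uk_tariff() -> ValueSet:
    """The packaged UK-style time-trade-off tariff."""
    ref = resources.files("dialcea").joinpath("data/uk_tto_tariff.yaml")
    with resources.as_file(ref) as path:
        return load_value_set(path)


def profile_scores(value_set: ValueSet) -> pd.DataFrame:
    """All 243 profiles with their scored utilities, sorted by utility."""
    rows = [
        {"profile": p, "utility": score_eq5d(p, value_set)}
        for p in product((1, 2, 3), repeat=5)
    ]
    return pd.DataFrame(rows).sort_values("utility", ignore_index=True)


def utility_to_profile(utility: float, value_set: ValueSet) -> tuple[int, ...]:
    """The scorable profile whose tariff value is nearest ``utility``.

    The returned profile's score is within one scoring step of the input by
    construction (nearest neighbour on the sorted score table); ties go to the
    lower-utility profile for determinism.
    """
    table = profile_scores(value_set)
    idx = (table["utility"] - utility).abs().idxmin()
    return tuple(table.loc[idx, "profile"])


@dataclass
class UtilityCurve:
    """Mean utility by months of dialysis vintage on a fixed monthly grid."""

    grid: np.ndarray
    u: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=int)
        self.u = np.asarray(self.u, dtype=float)
        if self.grid.shape != self.u.shape:
            raise ValueError("grid and utility arrays must have equal length")

    def at(self, months) -> np.ndarray:
        """Utility at the requested grid months (must lie on the grid)."""
        months = np.asarray(months, dtype=int)
        pos = np.searchsorted(self.grid, months)
        if (pos >= len(self.grid)).any() or (self.grid[np.minimum(pos, len(self.grid) - 1)] != months).any():
            raise ValueError("requested months not on the utility curve's grid")
        return self.u[pos]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"month": self.grid, "utility": self.u})


def smooth_utility(records: pd.DataFrame, grid) -> UtilityCurve:
    """Nearest-neighbour kernel smoother of utility against dialysis vintage.

    At each grid month ``t`` the estimate is the mean utility of the
    ``k = max(ceil(0.10 * n), 50)`` records nearest in ``|vintage - t|``;
    records tied with the k-th distance are all included, so the result is
    invariant to record order.

    Parameters
    ----------
    records:
        DataFrame with columns ``vintage`` (months) and ``utility``.
    grid:
        Months at which to evaluate the smoothed curve.

    Raises
    ------
    ValueError
        If fewer than 50 records are supplied — below the sampling floor the
        nearest-10% average is not considered a stable estimate.
    """
    n = len(records)
    if n < MIN_SMOOTHING_N:
        raise ValueError(
            f"kernel smoothing requires at least {MIN_SMOOTHING_N} utility records, got {n}"
        )
    vintages = records["vintage"].to_numpy(dtype=float)
    utilities = records["utility"].to_numpy(dtype=float)
    k = max(math.ceil(0.10 * n), MIN_SMOOTHING_N)
    grid = np.asarray(grid, dtype=int)
    out = np.empty(len(grid), dtype=float)
    for i, t in enumerate(grid):
        dist = np.abs(vintages - t)
        kth = np.partition(dist, k - 1)[k - 1]
        out[i] = utilities[dist <= kth].mean()
    return UtilityCurve(grid=grid, u=out, k=k)


def extend_utility(curve: UtilityCurve, horizon: int) -> UtilityCurve:
    """Extend a utility curve to ``horizon`` months, flat at its last value.

    Beyond the longest observed vintage the mean quality of life is assumed
    constant at its end-of-follow-up level.
    """
    if len(curve.grid) == 0:
        raise ValueError("cannot extend an empty utility curve")
    last = int(curve.grid[-1])
    if horizon <= last:
        return curve
    extra = np.arange(last + 1, horizon + 1)
    return UtilityCurve(
        grid=np.concatenate([curve.grid, extra]),
        u=np.concatenate([curve.u, np.full(len(extra), curve.u[-1])]),
        k=curve.k,
    )
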