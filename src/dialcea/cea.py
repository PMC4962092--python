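"""Cost curves, discounting, and the QALE / lifetime-cost / ICER arithmetic.

All integrals share one monthly bookkeeping convention: a quantity defined per
month ``t`` (survival probability, mean utility, mean cost, discount factor)
is summed over ``t = 1..horizon``, with areas in years divided by 12.

* Lifetime cost      ``= sum_t S(t) * c(t) * d(t)``       (currency units)
* QALE               ``= sum_t S(t) * u(t) * d(t) / 12``  (quality-adjusted life years)
* Cost per QALY      ``= lifetime cost / discounted QALE``
* ICER (a vs b)      ``= (cost_a - cost_b) / (QALE_a - QALE_b)``

Discounting is annual-step compound discounting at the configured rate,
starting at the end of the observed window (costs and utilities inside the
data period are taken at face value; only the extrapolated tail is
discounted).  Costs are first deflated to a base currency year with a CPI
series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qol import UtilityCurve
from .survival import SurvivalCurve, MONTHS_PER_YEAR

__all__ = [
    "CostCurve",
    "CEAConfig",
    "cpi_adjust",
    "mean_monthly_cost",
    "extend_cost",
    "discount_factors",
    "lifetime_cost",
    "qale",
    "cost_per_qaly",
    "icer",
    "IcerResult",
    "gdp_fold",
]


@dataclass
class CostCurve:
    """Mean monthly cost by months since index, split inpatient/outpatient."""

    grid: np.ndarray  # months since index, 1-based
    inpatient: np.ndarray
    outpatient: np.ndarray
    currency_year: int | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=int)
        self.inpatient = np.asarray(self.inpatient, dtype=float)
        self.outpatient = np.asarray(self.outpatient, dtype=float)
        if not (len(self.grid) == len(self.inpatient) == len(self.outpatient)):
            raise ValueError("cost curve arrays must share a length")
        if (self.inpatient < 0).any() or (self.outpatient < 0).any():
            raise ValueError("costs must be >= 0")

    @property
    def total(self) -> np.ndarray:
        return self.inpatient + self.outpatient

    @property
    def outpatient_share(self) -> np.ndarray:
        tot = self.total
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.outpatient / tot, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": self.grid,
                "inpatient": self.inpatient,
                "outpatient": self.outpatient,
                "total": self.total,
                "outpatient_share": self.outpatient_share,
            }
        )


@dataclass
class CEAConfig:
    """Economic settings: discount rate, horizon, currency base year, CPI."""

    discount_rate: float = 0.03
    discount_start_month: int = 0  # months <= start are undiscounted
    horizon_months: int = 720
    base_year: int = 2010
    cpi: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError("discount rate must be >= 0")
        if self.horizon_months < 1:
            raise ValueError("horizon must be >= 1 month")


def cpi_adjust(records: pd.DataFrame, cpi: dict[int, float], base_year: int) -> pd.DataFrame:
    """Deflate cost records to base-year currency: cost * CPI(base) / CPI(year).

    ``records`` needs ``year``, ``inpatient`` and ``outpatient`` columns; a
    missing CPI entry for any year present (or the base year) is an error.
    """
    if base_year not in cpi:
        raise ValueError(f"CPI series lacks the base year {base_year}")
    years = records["year"].unique()
    missing = [int(y) for y in years if y not in cpi]
    if missing:
        raise ValueError(f"CPI series lacks calendar years: {sorted(missing)}")
    factor = records["year"].map(cpi).rdiv(cpi[base_year]).to_numpy()
    out = records.copy()
    out["inpatient"] = out["inpatient"] * factor
    out["outpatient"] = out["outpatient"] * factor
    return out


def mean_monthly_cost(
    records: pd.DataFrame, currency_year: int | None = None
) -> CostCurve:
    """Average monthly cost over the subjects contributing records that month."""
    g = records.groupby("month")[["inpatient", "outpatient"]].mean().sort_index()
    return CostCurve(
        grid=g.index.to_numpy(),
        inpatient=g["inpatient"].to_numpy(),
        outpatient=g["outpatient"].to_numpy(),
        currency_year=currency_year,
    )


def extend_cost(curve: CostCurve, horizon: int, carry_window: int = 12) -> CostCurve:
    """Extend a cost curve to the horizon, carrying forward the mean of the
    last ``carry_window`` observed months (component-wise)."""
    last = int(curve.grid[-1])
    if horizon <= last:
        return curve
    w = min(carry_window, len(curve.grid))
    extra = np.arange(last + 1, horizon + 1)
    return CostCurve(
        grid=np.concatenate([curve.grid, extra]),
        inpatient=np.concatenate([curve.inpatient, np.full(len(extra), curve.inpatient[-w:].mean())]),
        outpatient=np.concatenate([curve.outpatient, np.full(len(extra), curve.outpatient[-w:].mean())]),
        currency_year=curve.currency_year,
    )


def discount_factors(grid, config: CEAConfig) -> np.ndarray:
    """Annual-step discount factor per month.

    Months at or before ``discount_start_month`` are undiscounted; a month
    ``t`` beyond it is discounted by ``(1+rate)^(-ceil((t-start)/12))``.
    """
    if config.discount_rate < 0:
        raise ValueError("discount rate must be >= 0")
    grid = np.asarray(grid, dtype=int)
    years_out = np.ceil(np.maximum(grid - config.discount_start_month, 0) / 12.0)
    return (1.0 + config.discount_rate) ** (-years_out)


def _align(surv: SurvivalCurve, grid: np.ndarray, horizon: int) -> np.ndarray:
    if int(surv.grid[-1]) < horizon:
        raise ValueError("survival curve does not reach the horizon")
    if grid[0] != 1 or int(grid[-1]) < horizon or not np.array_equal(grid[:horizon], np.arange(1, horizon + 1)):
        raise ValueError("curve grid must cover months 1..horizon")
    return surv.S[1: horizon + 1]


def lifetime_cost(
    surv: SurvivalCurve, cost: CostCurve, factors: np.ndarray, horizon: int | None = None
) -> float:
    """Survival-weighted, discounted lifetime cost: sum of S(t) c(t) d(t)."""
    if horizon is None:
        horizon = int(surv.grid[-1])
    S = _align(surv, cost.grid, horizon)
    if len(factors) < horizon:
        raise ValueError("discount factors do not cover the horizon")
    return float(np.sum(S * cost.total[:horizon] * factors[:horizon]))


def qale(
    surv: SurvivalCurve, util: UtilityCurve, factors: np.ndarray, horizon: int | None = None
) -> float:
    """Quality-adjusted life expectancy in QALYs: sum of S(t) u(t) d(t) / 12."""
    if horizon is None:
        horizon = int(surv.grid[-1])
    ugrid = util.grid if util.grid[0] == 1 else util.grid[util.grid >= 1]
    uvals = util.u[-len(ugrid):]
    S = _align(surv, ugrid, horizon)
    if len(factors) < horizon:
        raise ValueError("discount factors do not cover the horizon")
    return float(np.sum(S * uvals[:horizon] * factors[:horizon]) / MONTHS_PER_YEAR)


def cost_per_qaly(lifetime_cost_value: float, discounted_qale: float) -> float:
    """Cost-effectiveness ratio: lifetime cost over discounted QALE."""
    if discounted_qale <= 0:
        raise ValueError("cost per QALY requires a positive QALE denominator")
    return lifetime_cost_value / discounted_qale


@dataclass
class IcerResult:
    """Incremental cost-effectiveness comparison of arm a against arm b."""

    icer: float  # nan when the QALE difference is 0
    flag: str  # 'a dominant' | 'b dominant' | 'a cost-dominant' | 'b cost-dominant' | 'tradeoff'
    cost_diff: float
    qale_diff: float


def icer(cost_a: float, qale_a: float, cost_b: float, qale_b: float) -> IcerResult:
    """ICER = (cost_a - cost_b) / (qale_a - qale_b), with a dominance flag.

    Arm a *dominates* when it is both cheaper and more effective (negative
    ICER of the informative kind); with exactly equal QALE the ratio is
    undefined and the cheaper arm is flagged cost-dominant, with only the
    cost difference to report.  Degenerate cases are flagged, never raised.
    """
    dc, dq = cost_a - cost_b, qale_a - qale_b
    if dq == 0:
        value = math.nan
        if dc < 0:
            flag = "a cost-dominant"
        elif dc > 0:
            flag = "b cost-dominant"
        else:
            flag = "equivalent"
    else:
        value = dc / dq
        if dc < 0 and dq > 0:
            flag = "a dominant"
        elif dc > 0 and dq < 0:
            flag = "b dominant"
        else:
            flag = "tradeoff"
    return IcerResult(icer=value, flag=flag, cost_diff=dc, qale_diff=dq)


def gdp_fold(cost_per_qaly_value: float, gdp_per_capita: float) -> float:
    """Cost per QALY as a multiple of GDP per capita, to 2 decimals.

    The conventional cost-effectiveness yardstick: ratios below 1-3 times GDP
    per capita are considered cost-effective.
    """
    if gdp_per_capita <= 0:
        raise ValueError("GDP per capita must be > 0")
    return round(cost_per_qaly_value / gdp_per_capita, 2)
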