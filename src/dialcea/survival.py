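"""Within-sample survival, lifetime extrapolation and restricted-mean life expectancy.

The estimator chain is the relative-survival construction used to turn a
censored 14-year follow-up into a lifetime (720-month) survival curve:

1. Kaplan-Meier product-limit survival of the study cohort on a monthly grid.
2. An Ederer-style *expected* survival curve for an age- and sex-matched
   reference population, averaged over the cohort's individual life-table
   trajectories.
3. The relative survival ``W(t) = S_study(t) / S_ref(t)``.  Under the
   constant-excess-hazard assumption — the cohort's hazard exceeds the
   reference hazard by a constant ``lambda`` — ``W(t) = exp(-lambda * t)``,
   so a transform of W is linear in t.  A straight line fitted to the
   transformed W over the fit window is extrapolated beyond follow-up and
   back-transformed; the lifetime curve is the Kaplan-Meier estimate inside
   follow-up and ``g(a + b t) * S_ref(t)`` beyond it.

The default transform is the logarithm, under which the constant-excess-hazard
model is *exactly* linear with a zero intercept (``W(0) = 1`` identically), so
the default fit is a regression through the origin over the whole follow-up —
in simulation benchmarks this anchored fit recovers lifetime LE with visibly
smaller error spread than a free-intercept fit on the late window.  The logit
variant (equivalent for small W, bounded above by construction, but divergent
at W = 1) is available via ``transform="logit"``; it uses a free intercept
fitted over the second half of follow-up by default.  Window and intercept
remain configurable for data where early follow-up departs from the
constant-excess assumption.

Life expectancy is the restricted mean: the area under the survival curve to
the horizon by a monthly rectangle rule, reported in years.  Standard errors
come from a subject-level nonparametric bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.special import expit, logit as _logit

from .lifetable import LifeTable

logger = logging.getLogger(__name__)

MONTHS_PER_YEAR = 12
DEFAULT_HORIZON = 720
W_CLIP_EPS = 1e-6

__all__ = [
    "SurvivalCurve",
    "ExtrapolationFit",
    "kaplan_meier",
    "logrank_test",
    "reference_survival",
    "extrapolate_survival",
    "restricted_mean",
    "bootstrap_se",
]


@dataclass
class SurvivalCurve:
    """Survival probabilities on a monthly grid starting at 0."""

    grid: np.ndarray
    S: np.ndarray
    at_risk: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=int)
        self.S = np.asarray(self.S, dtype=float)
        if self.grid.shape != self.S.shape:
            raise ValueError("grid and survival arrays must have equal length")
        if len(self.grid) == 0 or self.grid[0] != 0:
            raise ValueError("survival grid must start at month 0")
        if abs(self.S[0] - 1.0) > 1e-12:
            raise ValueError("S(0) must equal 1")
        if (self.S < -1e-12).any() or (self.S > 1 + 1e-12).any():
            raise ValueError("survival probabilities must lie in [0,1]")
        if (np.diff(self.S) > 1e-12).any():
            raise ValueError("survival must be nonincreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"month": self.grid, "survival": self.S})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalCurve":
        return cls(grid=df["month"].to_numpy(), S=df["survival"].to_numpy())


def kaplan_meier(times, events, grid=None) -> SurvivalCurve:
    """Product-limit survival estimate evaluated on a monthly grid.

    ``times`` are months from index (continuous allowed); ``events`` is True
    for deaths, False for censoring.  The default grid runs monthly from 0 to
    the last observed time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValueError("cannot estimate survival from an empty cohort")
    if (times < 0).any():
        raise ValueError("negative survival times")
    if grid is None:
        grid = np.arange(int(np.ceil(times.max())) + 1)
    grid = np.asarray(grid, dtype=int)
    km = KaplanMeierFitter().fit(times, events, timeline=grid)
    S = km.survival_function_.iloc[:, 0].to_numpy()
    at_risk = np.asarray([(times >= t).sum() for t in grid])
    return SurvivalCurve(grid=grid, S=S, at_risk=at_risk)


def logrank_test(times1, events1, times2, events2) -> tuple[float, float]:
    """Two-group log-rank test (1 df); returns (chi-square statistic, p-value)."""
    if len(np.atleast_1d(times1)) == 0 or len(np.atleast_1d(times2)) == 0:
        raise ValueError("log-rank test requires both groups to be non-empty")
    res = _ll_logrank(times1, times2, event_observed_A=events1, event_observed_B=events2)
    return float(res.test_statistic), float(res.p_value)


def reference_survival(
    profiles: pd.DataFrame,
    life_table: LifeTable,
    horizon: int = DEFAULT_HORIZON,
    monte_carlo: bool = False,
    n_replicates: int = 10,
    seed: int = 0,
) -> SurvivalCurve:
    """Expected survival of an age- and sex-matched reference population.

    The default is the deterministic Ederer-style average: each subject
    contributes the life-table survival trajectory started at their index age,
    ``S_ref(t) = mean_i exp(-sum_{u<t} h(age_i + u, sex_i))``.  With
    ``monte_carlo=True`` the curve is instead the Kaplan-Meier estimate of
    simulated referent death times (``n_replicates`` referents per subject),
    retained as a fidelity check on the deterministic mode.
    """
    ages = profiles["age_at_index"].to_numpy(dtype=float)
    sexes = profiles["sex"].to_numpy()
    haz = life_table.hazard_paths(ages, sexes, horizon)
    cum = np.concatenate([np.zeros((len(ages), 1)), np.cumsum(haz, axis=1)], axis=1)
    if not monte_carlo:
        return SurvivalCurve(grid=np.arange(horizon + 1), S=np.exp(-cum).mean(axis=0))
    rng = np.random.default_rng(seed)
    cum_rep = np.repeat(cum[:, 1:], n_replicates, axis=0)
    H0 = np.concatenate([np.zeros((cum_rep.shape[0], 1)), cum_rep], axis=1)
    target = rng.exponential(size=cum_rep.shape[0])
    died = target <= H0[:, -1]
    t = np.full(cum_rep.shape[0], float(horizon))
    idx = np.where(died)[0]
    cols = np.array([np.searchsorted(H0[i], target[i]) for i in idx], dtype=int)
    h = H0[idx, cols] - H0[idx, cols - 1]
    t[idx] = (cols - 1) + (target[idx] - H0[idx, cols - 1]) / h
    return kaplan_meier(t, died, grid=np.arange(horizon + 1))


_TRANSFORMS: dict[str, tuple[Callable, Callable]] = {
    "log": (np.log, np.exp),
    "logit": (lambda w: _logit(np.clip(w, None, 1 - 1e-12)), expit),
}


@dataclass
class ExtrapolationFit:
    """A fitted lifetime survival extrapolation."""

    W: np.ndarray  # relative survival on the follow-up grid
    fit_window: tuple[int, int]
    transform: str
    slope: float
    intercept: float  # 0.0 for the origin-anchored fit
    fit_intercept: bool
    curve: SurvivalCurve  # lifetime curve on 0..horizon

    @property
    def monthly_excess_hazard(self) -> float:
        """-slope: the implied constant excess hazard (exact for the log transform)."""
        return -self.slope


def extrapolate_survival(
    km: SurvivalCurve,
    ref: SurvivalCurve,
    horizon: int = DEFAULT_HORIZON,
    fit_window: tuple[int, int] | None = None,
    transform: str = "log",
    fit_intercept: bool | None = None,
) -> ExtrapolationFit:
    """Extrapolate a follow-up survival curve to a lifetime horizon.

    Within follow-up the output equals the Kaplan-Meier curve; beyond it,
    ``S(t) = g(a + b*t) * S_ref(t)`` where ``a, b`` come from a least-squares
    line through the transformed relative survival on months in ``fit_window``
    and ``g`` inverts the transform.  For the default log transform the line
    is anchored at the origin (``a = 0``, since ``W(0) = 1`` exactly under
    the model) and the window spans the whole follow-up; for the logit
    transform the intercept is free and the window defaults to the second
    half of follow-up.  The assembled curve is forced nonincreasing by a
    running minimum.

    ``ref`` must cover months 0..horizon and be positive on the follow-up
    grid; ``km`` needs at least 24 months of follow-up.
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; choose from {sorted(_TRANSFORMS)}")
    if fit_intercept is None:
        fit_intercept = transform == "logit"
    if transform == "logit" and not fit_intercept:
        raise ValueError("the origin-anchored fit requires the log transform (logit(1) diverges)")
    T = int(km.grid[-1])
    if T < 24:
        raise ValueError("extrapolation requires at least 24 months of follow-up")
    if int(ref.grid[-1]) < horizon:
        raise ValueError("reference curve must extend to the horizon")
    if not np.array_equal(ref.grid[: T + 1], km.grid):
        raise ValueError("Kaplan-Meier and reference curves must share the follow-up grid")
    ref_follow = ref.S[: T + 1]
    if (ref_follow <= 0).any():
        raise ValueError("reference survival reaches 0 inside follow-up")
    if fit_window is None:
        fit_window = (T // 2, T) if transform == "logit" else (0, T)
    lo, hi = int(fit_window[0]), int(fit_window[1])
    if hi - lo < 6:
        raise ValueError("fit window must span at least 6 months")
    if lo < 0 or hi > T:
        raise ValueError("fit window must lie inside follow-up")

    # Floor-clip W before the transform. The upper end is clipped only for the
    # logit transform (which needs W < 1); under the log transform, chance
    # excursions of the Kaplan-Meier curve above the reference (W > 1) are kept,
    # since censoring them would bias the fitted slope downward when the true
    # excess hazard is near zero.
    W = km.S / ref_follow
    upper = 1.0 if transform == "logit" else np.inf
    n_clipped = int((W < W_CLIP_EPS).sum() + (W > upper).sum())
    if n_clipped:
        logger.warning("relative survival clipped at %d grid points", n_clipped)
    W = np.clip(W, W_CLIP_EPS, upper)

    fwd, inv = _TRANSFORMS[transform]
    tt = np.arange(lo, hi + 1)
    x = fwd(W[lo: hi + 1])
    if fit_intercept:
        slope, intercept = np.polyfit(tt, x, 1)
    else:
        slope, intercept = float(tt @ x) / float(tt @ tt), 0.0

    tail_months = np.arange(T + 1, horizon + 1)
    g = np.clip(inv(intercept + slope * tail_months), 0.0, 1.0)
    S_full = np.concatenate([km.S, g * ref.S[T + 1:]])
    S_full = np.minimum.accumulate(S_full)
    curve = SurvivalCurve(grid=np.arange(horizon + 1), S=S_full)
    return ExtrapolationFit(
        W=W, fit_window=(lo, hi), transform=transform,
        slope=float(slope), intercept=float(intercept),
        fit_intercept=fit_intercept, curve=curve,
    )


def restricted_mean(curve: SurvivalCurve, horizon: int | None = None) -> float:
    """Restricted-mean life expectancy in years: sum of monthly survival / 12.

    Uses the right-endpoint monthly rectangle rule,
    ``LE = sum_{t=1..horizon} S(t) / 12`` — the same bookkeeping the cost and
    quality-adjustment integrals use.
    """
    if horizon is None:
        horizon = int(curve.grid[-1])
    if horizon > curve.grid[-1]:
        raise ValueError("horizon beyond the survival curve's grid")
    return float(curve.S[1: horizon + 1].sum() / MONTHS_PER_YEAR)


def bootstrap_se(
    data: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], float],
    B: int = 100,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Subject-level nonparametric bootstrap SE and 95% percentile interval.

    Draws ``B`` resamples of the rows of ``data`` with replacement, applies
    ``statistic`` to each, and returns the standard deviation of the replicate
    values together with the (2.5, 97.5) percentile interval.
    """
    if B < 2:
        raise ValueError("bootstrap requires B >= 2 resamples")
    rng = np.random.default_rng(seed)
    n = len(data)
    values = np.empty(B)
    for b in range(B):
        take = rng.integers(0, n, size=n)
        values[b] = statistic(data.iloc[take])
    se = float(values.std(ddof=1))
    ci = (float(np.percentile(values, 2.5)), float(np.percentile(values, 97.5)))
    return se, ci
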