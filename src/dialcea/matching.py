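"""Propensity-score estimation, exact+caliper matching and balance diagnostics.

The propensity score is the modeled probability of receiving the scarcer
modality (PD) given baseline covariates, fitted by maximum-likelihood
logistic regression.  Matching is greedy nearest-neighbour without
replacement: cases are processed in seeded-random order and each is paired
with the eligible control (sharing all exact variables, inside every caliper)
whose propensity score is closest, ties broken by smallest subject id.  A
2:1 sensitivity mode pairs each case with its two nearest controls.

Covariate balance is quantified with the standardized difference ``di`` in
percentage points::

    binary:      di = 100 |p1 - p2| / sqrt((p1(1-p1) + p2(1-p2)) / 2)
    continuous:  di = 100 |m1 - m2| / sqrt((s1^2 + s2^2) / 2)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "MatchSpec",
    "PropensityFit",
    "MatchedCohort",
    "fit_propensity",
    "match_cohort",
    "standardized_difference",
    "balance_table",
]


@dataclass
class MatchSpec:
    """Constraints for one matching run.

    ``exact`` variables must agree exactly between case and control;
    ``calipers`` maps a numeric variable to the maximum absolute difference
    allowed (e.g. ``{"age_at_index": 2.0}``); ``ps_caliper`` bounds the
    absolute propensity-score difference; ``ratio`` is controls per case.
    """

    exact: list[str] = field(default_factory=list)
    calipers: dict[str, float] = field(default_factory=dict)
    ps_caliper: float = 0.05
    ratio: int = 1

    def __post_init__(self) -> None:
        if self.ps_caliper <= 0:
            raise ValueError("propensity caliper must be > 0")
        for var, width in self.calipers.items():
            if width <= 0:
                raise ValueError(f"caliper for {var!r} must be > 0")
        if self.ratio not in (1, 2):
            raise ValueError("matching ratio must be 1 or 2")


@dataclass
class PropensityFit:
    scores: pd.Series
    params: pd.Series
    bse: pd.Series
    covariates: list[str]


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> None:
    for col in X.columns:
        x0, x1 = X.loc[y == 0, col], X.loc[y == 1, col]
        if len(x0) == 0 or len(x1) == 0:
            continue
        if x0.max() <= x1.min() or x1.max() <= x0.min():
            # identical-constant columns are collinearity, not separation
            if x0.nunique() == 1 and x1.nunique() == 1 and x0.iloc[0] == x1.iloc[0]:
                continue
            raise ValueError(
                f"complete separation: covariate {col!r} perfectly predicts the modality"
            )


def fit_propensity(
    cohort: pd.DataFrame, covariates: list[str], treatment: str = "PD"
) -> PropensityFit:
    """Logistic propensity model for assignment to ``treatment``.

    Returns fitted probabilities for every subject plus coefficients and
    standard errors.  An empty covariate list yields the intercept-only fit
    (every score equals the treatment fraction).  Complete separation is
    detected before fitting and reported with the offending covariate.
    """
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks propensity covariates: {missing}")
    y = (cohort["modality"] == treatment).to_numpy(dtype=float)
    X = cohort[list(covariates)].astype(float)
    if X.isna().any().any():
        raise ValueError("missing values in propensity covariates")
    _check_separation(X, y)
    design = sm.add_constant(X, has_constant="add")
    res = sm.Logit(y, design).fit(disp=0)
    scores = pd.Series(res.predict(design), index=cohort.index, name="propensity")
    return PropensityFit(
        scores=scores, params=res.params, bse=res.bse, covariates=list(covariates)
    )


@dataclass
class MatchedCohort:
    """Matched sets plus the flattened cohort view they induce."""

    sets: pd.DataFrame  # columns: set_id, case_id, control_id
    cohort: pd.DataFrame  # matched subjects only, original columns
    n_cases_unmatched: int
    spec: MatchSpec

    @property
    def n_sets(self) -> int:
        return int(self.sets["set_id"].nunique()) if len(self.sets) else 0


def match_cohort(
    cohort: pd.DataFrame,
    scores: pd.Series,
    spec: MatchSpec,
    seed: int = 0,
    case_modality: str = "PD",
) -> MatchedCohort:
    """Greedy nearest-neighbour matching without replacement.

    Cases (default: PD, the scarcer arm) are visited in seeded-random order;
    each is matched to its ``spec.ratio`` nearest controls by absolute
    propensity difference among controls that share every exact variable and
    sit inside every caliper.  Cases without enough eligible controls are
    dropped and counted.  No control is ever reused.
    """
    for var in spec.exact + list(spec.calipers):
        if var not in cohort.columns:
            raise ValueError(f"matching spec references missing variable {var!r}")
    work = cohort.copy()
    work["_ps"] = scores.reindex(cohort.index).to_numpy()
    if work["_ps"].isna().any():
        raise ValueError("propensity scores missing for some subjects")

    cases = work.loc[work["modality"] == case_modality]
    controls = work.loc[work["modality"] != case_modality]

    # bucket controls by exact-variable key for fast candidate lookup
    if spec.exact:
        buckets = {
            (key if isinstance(key, tuple) else (key,)): grp
            for key, grp in controls.groupby(list(spec.exact))
        }
    else:
        buckets = {(): controls}
    used: set = set()
    rng = np.random.default_rng(seed)
    order = rng.permutation(cases.index.to_numpy())

    rows = []
    n_unmatched = 0
    set_id = 0
    for ci in order:
        case = cases.loc[ci]
        key = tuple(case[v] for v in spec.exact) if spec.exact else ()
        cand = buckets.get(key)
        if cand is None:
            n_unmatched += 1
            continue
        mask = ~cand["id"].isin(used).to_numpy()
        ps_diff = np.abs(cand["_ps"].to_numpy() - case["_ps"])
        mask &= ps_diff <= spec.ps_caliper
        for var, width in spec.calipers.items():
            mask &= np.abs(cand[var].to_numpy() - case[var]) <= width
        elig = cand.loc[mask]
        if len(elig) < spec.ratio:
            n_unmatched += 1
            continue
        dist = np.abs(elig["_ps"].to_numpy() - case["_ps"])
        picked = elig.assign(_d=dist).sort_values(["_d", "id"]).head(spec.ratio)
        for _, ctl in picked.iterrows():
            rows.append({"set_id": set_id, "case_id": case["id"], "control_id": ctl["id"]})
            used.add(ctl["id"])
        set_id += 1

    sets = pd.DataFrame(rows, columns=["set_id", "case_id", "control_id"])
    matched_ids = set(sets["case_id"]).union(sets["control_id"]) if len(sets) else set()
    matched = cohort.loc[cohort["id"].isin(matched_ids)].reset_index(drop=True)
    return MatchedCohort(sets=sets, cohort=matched, n_cases_unmatched=n_unmatched, spec=spec)


def standardized_difference(
    summary1: tuple, summary2: tuple, binary: bool = True
) -> float:
    """Standardized difference di in percentage points.

    For binary variables pass ``(p,)`` proportions; for continuous pass
    ``(mean, sd)``.  Returns ``0.0`` when both variances vanish with equal
    means, ``inf`` when they vanish with unequal means.
    """
    if binary:
        (p1,), (p2,) = summary1, summary2
        if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
            raise ValueError("binary summaries must be proportions in [0,1]")
        pooled = (p1 * (1 - p1) + p2 * (1 - p2)) / 2.0
        num = abs(p1 - p2)
    else:
        (m1, s1), (m2, s2) = summary1, summary2
        pooled = (s1**2 + s2**2) / 2.0
        num = abs(m1 - m2)
    if pooled == 0:
        return 0.0 if num == 0 else math.inf
    return 100.0 * num / math.sqrt(pooled)


def _di_for(df1: pd.DataFrame, df2: pd.DataFrame, var: str) -> float:
    x1, x2 = df1[var], df2[var]
    vals = pd.concat([x1, x2]).dropna().unique()
    if set(np.unique(vals)).issubset({0, 1}):
        return standardized_difference((x1.mean(),), (x2.mean(),), binary=True)
    return standardized_difference(
        (x1.mean(), x1.std(ddof=1)), (x2.mean(), x2.std(ddof=1)), binary=False
    )


def balance_table(
    cohort: pd.DataFrame,
    matched: MatchedCohort,
    variables: list[str],
    case_modality: str = "PD",
) -> pd.DataFrame:
    """Pre- and post-match standardized differences, one row per variable.

    Binary variables (values in {0,1}) use the pooled-proportion-variance
    formula; other numeric variables the pooled-SD formula.  ``di`` columns
    are rounded to two decimals for reporting.
    """
    rows = []
    pre1 = cohort.loc[cohort["modality"] != case_modality]
    pre2 = cohort.loc[cohort["modality"] == case_modality]
    post1 = matched.cohort.loc[matched.cohort["modality"] != case_modality]
    post2 = matched.cohort.loc[matched.cohort["modality"] == case_modality]
    for var in variables:
        rows.append(
            {
                "variable": var,
                "mean_control_post": post1[var].mean() if len(post1) else np.nan,
                "mean_case_post": post2[var].mean() if len(post2) else np.nan,
                "di_pre": round(_di_for(pre1, pre2, var), 2),
                "di_post": round(_di_for(post1, post2, var), 2),
            }
        )
    return pd.DataFrame(rows, columns=["variable", "mean_control_post", "mean_case_post", "di_pre", "di_post"])
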