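"""Synthetic national-cohort generator with known ground truth.

Emulates the data a matched dialysis cost-effectiveness study consumes —
person-level cohort table, pre-index claims, monthly cost streams and a
cross-sectional EQ-5D survey — from an explicit :class:`~dialcea.config.SimulationConfig`,
so that every downstream estimator can be checked against the parameters that
generated the data.

The survival model is exactly the one the lifetime extrapolation assumes:
each subject's monthly mortality hazard is the age-sex reference hazard from
the life table plus a constant modality-specific excess hazard.  Death times
are drawn by inverse transform on the piecewise-constant monthly hazard, so
generated survival matches ``exp(-(H_ref(t) + lambda*t))`` exactly in
expectation.

All randomness flows from one global seed, expanded into independent
per-stream sub-seeds (subjects / claims / costs / survey) so each table can be
regenerated on its own.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import COVARIATES, SimulationConfig
from .lifetable import LifeTable
from .qol import ValueSet, profile_scores

_STREAMS = {"subjects": 1, "claims": 2, "costs": 3, "survey": 4}

__all__ = [
    "stream_rng",
    "generate_subjects",
    "generate_claims",
    "generate_cost_streams",
    "generate_eq5d_survey",
    "ground_truth_survival",
]


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one data stream, derived from the global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


def _draw_death_times(
    cum_hazard: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-transform sampling on piecewise-constant monthly hazards.

    ``cum_hazard`` is (n, T) cumulative hazard at the end of each month.
    Returns continuous death times in months and a boolean 'died within T'.
    """
    n, T = cum_hazard.shape
    H0 = np.concatenate([np.zeros((n, 1)), cum_hazard], axis=1)
    target = rng.exponential(size=n)
    died = target <= H0[:, -1]
    times = np.full(n, float(T))
    idx = np.where(died)[0]
    # month containing the target cumulative hazard, then linear within month
    cols = np.array([np.searchsorted(H0[i], target[i]) for i in idx], dtype=int)
    h_month = H0[idx, cols] - H0[idx, cols - 1]
    frac = (target[idx] - H0[idx, cols - 1]) / h_month
    times[idx] = (cols - 1) + frac
    return times, died


def generate_subjects(config: SimulationConfig, life_table: LifeTable) -> pd.DataFrame:
    """Generate the raw person-level cohort table.

    Covariate flags are Bernoulli draws at the configured prevalences; the
    modality is PD with probability ``expit`` of the true propensity linear
    predictor; death times come from the reference hazard plus the constant
    modality excess hazard, administratively censored at the horizon.

    A configurable sliver of subjects is planted to violate each eligibility
    rule (underage, <= 3 months of dialysis, malignancy, sustained modality
    switch, transplantation before dialysis), and another to be transplanted
    during follow-up; the eligibility filter must catch all of them.

    Returns a DataFrame with one row per subject; columns include the
    covariate flags, ``time`` (months from index, continuous), ``event``
    ('death'/'censored') and the history fields the eligibility rules read
    (``dialysis_months``, ``switch_months``, ``malignancy``,
    ``prior_transplant``, ``transplant_month``).
    """
    config.validate()
    if config.censor_horizon_months < 1:
        raise ValueError("censor horizon must be >= 1 month")
    rng = stream_rng(config.seed, "subjects")
    n = config.n_subjects

    ages = np.clip(rng.normal(config.age_mean, config.age_sd, n), *config.age_range)
    sexes = np.where(rng.random(n) < config.p_male, "M", "F")
    flags = {
        c: (rng.random(n) < config.covariate_prevalence.get(c, 0.0)).astype(int)
        for c in COVARIATES
    }
    lp = np.full(n, config.propensity_intercept)
    for c, beta in config.propensity_coefficients.items():
        lp += beta * flags[c]
    p_pd = 1.0 / (1.0 + np.exp(-lp))
    modality = np.where(rng.random(n) < p_pd, "PD", "HD")

    urban = rng.choice([0, 1, 2], size=n, p=config.urbanization_probs)
    y0, y1 = config.accrual_years
    index_year = rng.integers(y0, y1 + 1, size=n)
    index_month = rng.integers(1, 13, size=n)

    # planted ineligibility, on disjoint subject slices
    order = rng.permutation(n)
    frac = config.ineligible
    sizes = [
        int(round(f * n))
        for f in (
            frac.underage,
            frac.short_dialysis,
            frac.malignancy,
            frac.modality_switch,
            frac.prior_transplant,
            frac.transplant_during_followup,
        )
    ]
    cuts = np.cumsum([0] + sizes)
    sl = [order[cuts[i]: cuts[i + 1]] for i in range(len(sizes))]
    underage, short_dial, malig, switch, prior_tx, tx_during = sl

    ages[underage] = rng.uniform(16.0, 18.0, size=len(underage))

    T = config.censor_horizon_months
    lam = np.where(modality == "PD", config.excess_hazard["PD"], config.excess_hazard["HD"])
    haz = life_table.hazard_paths(ages, sexes, T) + lam[:, None]
    times, died = _draw_death_times(np.cumsum(haz, axis=1), rng)

    dialysis_months = 3.0 + times
    dialysis_months[short_dial] = rng.uniform(0.5, 3.0, size=len(short_dial))
    switch_months = np.zeros(n)
    switch_months[switch] = rng.uniform(4.0, 12.0, size=len(switch))
    malignancy = np.zeros(n, dtype=bool)
    malignancy[malig] = True
    prior_transplant = np.zeros(n, dtype=bool)
    prior_transplant[prior_tx] = True
    transplant_month = np.full(n, np.nan)
    transplant_month[tx_during] = rng.uniform(1.0, 0.999 * np.maximum(times[tx_during], 1.5))

    cohort = pd.DataFrame(
        {
            "id": np.arange(n),
            "age_at_index": ages,
            "sex": sexes,
            "index_year": index_year,
            "index_month": index_month,
            "modality": modality,
            "time": times,
            "event": np.where(died, "death", "censored"),
            "urbanization": urban,
            **flags,
            "dialysis_months": dialysis_months,
            "switch_months": switch_months,
            "malignancy": malignancy,
            "prior_transplant": prior_transplant,
            "transplant_month": transplant_month,
        }
    )
    return cohort


def _index_dates(cohort: pd.DataFrame) -> pd.Series:
    return pd.to_datetime(
        {
            "year": cohort["index_year"],
            "month": cohort["index_month"],
            "day": 1,
        }
    ).set_axis(cohort["id"])


def generate_claims(
    cohort: pd.DataFrame,
    config: SimulationConfig,
    code_map: dict[str, tuple[str, ...]],
    decoy_rate: float = 0.25,
) -> pd.DataFrame:
    """Emit pre-index claims realizing each subject's true comorbidity flags.

    For every true flag the subject gets either one inpatient discharge claim
    or two ambulatory claims >= 30 days apart, all inside the 365-day window
    before the index date.  For a fraction of *false* flags, decoy claims are
    planted that must not satisfy the ascertainment rule: a single ambulatory
    visit, an ambulatory pair < 30 days apart, or a pair whose earlier claim
    falls outside the one-year window.

    Columns: ``id``, ``date``, ``setting`` ('inpatient'/'ambulatory'), ``code``.
    """
    rng = stream_rng(config.seed, "claims")
    index = _index_dates(cohort)
    out_id, out_off, out_setting, out_code = [], [], [], []

    def emit(ids, offsets_days, setting, comorbidity):
        prefixes = code_map[comorbidity]
        for sid, off in zip(ids, offsets_days):
            out_id.append(sid)
            out_off.append(int(off))
            out_setting.append(setting)
            out_code.append(prefixes[rng.integers(len(prefixes))] + str(rng.integers(10)))

    for comorbidity in code_map:
        if comorbidity not in cohort.columns:
            continue
        truthy = cohort.loc[cohort[comorbidity] == 1, "id"].to_numpy()
        pattern = rng.random(len(truthy)) < 0.5
        inpat = truthy[pattern]
        emit(inpat, rng.integers(10, 350, size=len(inpat)), "inpatient", comorbidity)
        ambu = truthy[~pattern]
        off2 = rng.integers(1, 120, size=len(ambu))
        gap = rng.integers(30, 200, size=len(ambu))
        emit(ambu, off2, "ambulatory", comorbidity)
        emit(ambu, off2 + gap, "ambulatory", comorbidity)

        falsy = cohort.loc[cohort[comorbidity] == 0, "id"].to_numpy()
        falsy = falsy[rng.random(len(falsy)) < decoy_rate]
        kind = rng.integers(3, size=len(falsy))
        single = falsy[kind == 0]
        emit(single, rng.integers(1, 350, size=len(single)), "ambulatory", comorbidity)
        close = falsy[kind == 1]
        c2 = rng.integers(1, 300, size=len(close))
        emit(close, c2, "ambulatory", comorbidity)
        emit(close, c2 + rng.integers(5, 30, size=len(close)), "ambulatory", comorbidity)
        stale = falsy[kind == 2]
        emit(stale, rng.integers(30, 300, size=len(stale)), "ambulatory", comorbidity)
        emit(stale, rng.integers(370, 500, size=len(stale)), "ambulatory", comorbidity)

    claims = pd.DataFrame(
        {
            "id": np.array(out_id, dtype=int),
            "offset": np.array(out_off, dtype=int),
            "setting": out_setting,
            "code": out_code,
        }
    )
    claims["date"] = index.loc[claims["id"]].to_numpy() - pd.to_timedelta(claims.pop("offset"), unit="D")
    return claims.sort_values(["id", "date"], ignore_index=True)[["id", "date", "setting", "code"]]


def generate_cost_streams(cohort: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Monthly cost records for every alive month of every subject.

    Outpatient costs are gamma noise around the modality mean (the recurring
    dialysis sessions); inpatient costs are sparse hospitalization spikes.
    Month 1 outpatient spending is scaled by the first-month multiplier
    (access placement).  A calendar year is attached for CPI adjustment.

    Columns: ``id``, ``month`` (1-based months since index), ``outpatient``,
    ``inpatient``, ``year``.  No record exists past a subject's death month.
    """
    rng = stream_rng(config.seed, "costs")
    cp = config.cost
    n_months = np.ceil(cohort["time"].to_numpy()).astype(int)
    n_months = np.maximum(n_months, (cohort["time"].to_numpy() > 0).astype(int))
    ids = np.repeat(cohort["id"].to_numpy(), n_months)
    modality = np.repeat(cohort["modality"].to_numpy(), n_months)
    month = np.concatenate([np.arange(1, m + 1) for m in n_months]) if len(n_months) else np.array([], int)
    index_ym = np.repeat(
        (cohort["index_year"].to_numpy() * 12 + cohort["index_month"].to_numpy() - 1), n_months
    )
    year = (index_ym + month - 1) // 12

    def noisy(mean: np.ndarray) -> np.ndarray:
        if cp.noise_cv == 0:
            return mean.astype(float)
        shape = 1.0 / cp.noise_cv**2
        return rng.gamma(shape, mean / shape)

    out_mean = np.where(modality == "PD", cp.outpatient_mean["PD"], cp.outpatient_mean["HD"])
    outpatient = noisy(out_mean)
    outpatient[month == 1] *= cp.first_month_multiplier
    event = rng.random(len(ids)) < cp.inpatient_event_rate
    in_mean = np.where(modality == "PD", cp.inpatient_event_mean["PD"], cp.inpatient_event_mean["HD"])
    inpatient = np.where(event, noisy(in_mean), 0.0)

    return pd.DataFrame(
        {"id": ids, "month": month, "outpatient": outpatient, "inpatient": inpatient, "year": year}
    )


def _nearest_profile_utilities(latent: np.ndarray, value_set: ValueSet) -> tuple[np.ndarray, np.ndarray]:
    """Snap latent utilities to the nearest scorable EQ-5D profile (vectorized)."""
    table = profile_scores(value_set)
    scores = table["utility"].to_numpy()
    profiles = np.array(table["profile"].tolist(), dtype=int)
    pos = np.searchsorted(scores, latent)
    pos = np.clip(pos, 1, len(scores) - 1)
    lower_closer = (latent - scores[pos - 1]) <= (scores[pos] - latent)
    pick = np.where(lower_closer, pos - 1, pos)
    return profiles[pick], scores[pick]


def generate_eq5d_survey(config: SimulationConfig, value_set: ValueSet) -> pd.DataFrame:
    """Cross-sectional EQ-5D survey across dialysis vintages.

    Latent utility = intercept + slope * vintage + covariate and modality
    effects + Gaussian noise, truncated to the value set's range, then mapped
    to the nearest scorable five-domain profile; the recorded ``utility`` is
    that profile's tariff score.  A 0-100 visual analogue scale correlated
    with the latent value is attached, along with the covariates used for
    cross-sectional matching.
    """
    up = config.utility
    rng = stream_rng(config.seed, "survey")
    n = up.n_records
    modality = np.where(rng.random(n) < up.pd_fraction, "PD", "HD")
    vintage = rng.integers(up.vintage_range[0], up.vintage_range[1] + 1, size=n)
    age = np.clip(rng.normal(52.0, 13.0, n), 20.0, 85.0)
    sex = np.where(rng.random(n) < config.p_male, "M", "F")
    covs = {
        c: (rng.random(n) < config.covariate_prevalence.get(c, 0.0)).astype(int)
        for c in up.covariate_effects
    }
    latent = up.intercept + up.slope_per_month * vintage
    for c, eff in up.covariate_effects.items():
        latent = latent + eff * covs[c]
    latent = latent + np.array([up.modality_effect[m] for m in modality])
    if up.noise_sd > 0:
        latent = latent + rng.normal(0.0, up.noise_sd, n)
    latent = np.clip(latent, value_set.min_value, 1.0)
    profiles, scored = _nearest_profile_utilities(latent, value_set)
    vas = np.clip(np.round(100 * (0.45 + 0.35 * latent) + rng.normal(0, 8, n)), 0, 100)

    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "modality": modality,
            "vintage": vintage,
            "age": age,
            "sex": sex,
            **covs,
        }
    )
    for j, dim in enumerate(("mobility", "self_care", "usual_activities", "pain_discomfort", "anxiety_depression")):
        df[dim] = profiles[:, j]
    df["utility"] = scored
    df["vas"] = vas.astype(int)
    return df


def ground_truth_survival(
    cohort: pd.DataFrame, life_table: LifeTable, lam: float, n_months: int
) -> np.ndarray:
    """Analytic cohort survival exp(-(H_ref(t) + lambda*t)) averaged over subjects.

    The independent oracle for extrapolation-recovery tests: numeric
    integration of the true hazard, bypassing every estimator in the package.
    Returns survival on months 0..n_months.
    """
    haz = life_table.hazard_paths(
        cohort["age_at_index"].to_numpy(), cohort["sex"].to_numpy(), n_months
    ) + lam
    cum = np.concatenate([np.zeros((len(cohort), 1)), np.cumsum(haz, axis=1)], axis=1)
    return np.exp(-cum).mean(axis=0)
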