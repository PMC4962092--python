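import numpy as np
import pandas as pd
import pytest

import dialcea as d
from dialcea.config import CostParams, UtilityParams

from conftest import clean_config


def test_generators_are_deterministic(life_table, uk_vs, small_config):
    a = d.synthetic.generate_subjects(small_config, life_table)
    b = d.synthetic.generate_subjects(small_config, life_table)
    pd.testing.assert_frame_equal(a, b)
    pd.testing.assert_frame_equal(
        d.synthetic.generate_claims(a, small_config, d.toy_code_map()),
        d.synthetic.generate_claims(b, small_config, d.toy_code_map()),
    )
    pd.testing.assert_frame_equal(
        d.synthetic.generate_cost_streams(a, small_config),
        d.synthetic.generate_cost_streams(b, small_config),
    )
    pd.testing.assert_frame_equal(
        d.synthetic.generate_eq5d_survey(small_config, uk_vs),
        d.synthetic.generate_eq5d_survey(small_config, uk_vs),
    )


def test_equal_hazards_give_overlapping_km_curves(life_table):
    cfg = clean_config(n_subjects=2000, seed=5, excess_hazard={"HD": 0.0, "PD": 0.0})
    coh = d.synthetic.generate_subjects(cfg, life_table)
    grid = np.arange(cfg.censor_horizon_months + 1)
    curves = {}
    for m in ("HD", "PD"):
        arm = coh[coh["modality"] == m]
        curves[m] = d.kaplan_meier(arm["time"], arm["event"] == "death", grid)
    assert np.abs(curves["HD"].S - curves["PD"].S).max() < 0.05


def test_symmetric_propensity_gives_half_pd(life_table):
    cfg = clean_config(
        n_subjects=4000, seed=2, propensity_intercept=0.0,
        propensity_coefficients={c: 0.0 for c in d.PS_COVARIATES},
    )
    coh = d.synthetic.generate_subjects(cfg, life_table)
    frac = (coh["modality"] == "PD").mean()
    tol = 3 * np.sqrt(0.25 / len(coh))
    assert abs(frac - 0.5) < tol


def test_pure_excess_hazard_exponential_survival():
    """With a negligible background hazard, 12-month survival is exp(-12*lambda)."""
    lt = d.build_life_table({"M": d.GompertzParams(1e-12, 0.0), "F": d.GompertzParams(1e-12, 0.0)})
    lam = 0.02
    cfg = clean_config(
        n_subjects=4000, seed=9, excess_hazard={"HD": lam, "PD": lam},
        age_mean=30.0, age_sd=5.0, age_range=(18.0, 45.0),
    )
    coh = d.synthetic.generate_subjects(cfg, lt)
    observed = (coh["time"] > 12).mean()
    expected = np.exp(-12 * lam)
    tol = 3 * np.sqrt(expected * (1 - expected) / len(coh))
    assert abs(observed - expected) < tol


def test_ground_truth_survival_recovery(life_table):
    """Empirical survival matches exp(-(H_ref + lambda t)) within binomial noise."""
    lam = 0.004
    cfg = clean_config(n_subjects=2500, seed=13, excess_hazard={"HD": lam, "PD": lam})
    coh = d.synthetic.generate_subjects(cfg, life_table)
    truth = d.synthetic.ground_truth_survival(coh, life_table, lam, cfg.censor_horizon_months)
    for t in (12, 60, 120, 168):
        observed = (coh["time"] > t).mean() if t < cfg.censor_horizon_months else (coh["time"] >= t).mean()
        tol = 3 * np.sqrt(truth[t] * (1 - truth[t]) / len(coh))
        assert abs(observed - truth[t]) < tol, f"month {t}"


def test_degenerate_cost_stream(life_table):
    cfg = clean_config(
        n_subjects=200, seed=4,
        cost=CostParams(
            outpatient_mean={"HD": 1000.0, "PD": 1000.0},
            inpatient_event_rate=0.0,
            first_month_multiplier=1.0,
            noise_cv=0.0,
        ),
    )
    coh = d.synthetic.generate_subjects(cfg, life_table)
    costs = d.synthetic.generate_cost_streams(coh, cfg)
    assert (costs["outpatient"] == 1000.0).all()
    assert (costs["inpatient"] == 0.0).all()


def test_no_costs_after_death(life_table, small_config):
    coh = d.synthetic.generate_subjects(small_config, life_table)
    costs = d.synthetic.generate_cost_streams(coh, small_config)
    last = costs.groupby("id")["month"].max()
    alive = coh.set_index("id")["time"]
    assert (last <= np.ceil(alive.loc[last.index]) + 1e-9).all()


def test_outpatient_share_near_ninety_percent(life_table):
    cfg = clean_config(n_subjects=2000, seed=21)
    coh = d.synthetic.generate_subjects(cfg, life_table)
    costs = d.synthetic.generate_cost_streams(coh, cfg)
    share = costs["outpatient"].sum() / (costs["outpatient"] + costs["inpatient"]).sum()
    assert 0.85 < share < 0.95


def test_survey_full_health_when_trajectory_saturates(uk_vs):
    cfg = clean_config(
        n_subjects=100, seed=3,
        utility=UtilityParams(intercept=1.5, slope_per_month=0.0, noise_sd=0.0,
                              covariate_effects={}, n_records=200),
    )
    survey = d.synthetic.generate_eq5d_survey(cfg, uk_vs)
    dims = ["mobility", "self_care", "usual_activities", "pain_discomfort", "anxiety_depression"]
    assert (survey[dims].to_numpy() == 1).all()
    assert (survey["utility"] == 1.0).all()


def test_survey_negative_slope_monotone(uk_vs):
    cfg = clean_config(
        n_subjects=100, seed=3,
        utility=UtilityParams(slope_per_month=-0.002, n_records=3000),
    )
    survey = d.synthetic.generate_eq5d_survey(cfg, uk_vs)
    tertiles = pd.qcut(survey["vintage"], 3, labels=["lo", "mid", "hi"])
    means = survey.groupby(tertiles, observed=True)["utility"].mean()
    assert means["hi"] <= means["lo"]


def test_survey_levels_scoreable(uk_vs, small_config):
    survey = d.synthetic.generate_eq5d_survey(small_config, uk_vs)
    dims = ["mobility", "self_care", "usual_activities", "pain_discomfort", "anxiety_depression"]
    rescored = survey[dims].apply(lambda r: d.score_eq5d(tuple(r), uk_vs), axis=1)
    assert np.allclose(rescored, survey["utility"])
    assert survey["vas"].between(0, 100).all()


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        d.SimulationConfig(censor_horizon_months=0)
    with pytest.raises(ValueError):
        d.SimulationConfig(excess_hazard={"HD": -0.01, "PD": 0.0})
    with pytest.raises(ValueError):
        d.SimulationConfig(covariate_prevalence={"diabetes": 1.4})


def test_config_yaml_round_trip(tmp_path, small_config):
    p = tmp_path / "cfg.yaml"
    small_config.to_yaml(p)
    again = d.SimulationConfig.from_yaml(p)
    assert again.to_dict() == small_config.to_dict()
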