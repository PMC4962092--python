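import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import dialcea as d
from conftest import clean_config, km_oracle


def test_km_no_deaths_is_unit():
    curve = d.kaplan_meier(np.full(10, 24.0), np.zeros(10, bool), np.arange(25))
    assert np.allclose(curve.S, 1.0)


def test_km_hand_computed_case():
    times = [2, 3, 3, 5, 7]
    events = [False, True, True, False, True]
    curve = d.kaplan_meier(times, events, np.arange(8))
    assert np.allclose(curve.S[:3], 1.0)
    assert curve.S[3] == pytest.approx(0.5)
    assert curve.S[5] == pytest.approx(0.5)
    assert curve.S[7] == pytest.approx(0.0)


def test_km_certain_death():
    curve = d.kaplan_meier([1.0, 1.0, 1.0], [True] * 3, np.arange(3))
    assert curve.S[1] == 0.0


def test_km_empty_rejected():
    with pytest.raises(ValueError):
        d.kaplan_meier([], [], np.arange(2))


@given(
    times=st.lists(st.sampled_from([0.5, 1.0, 1.5, 2.0, 3.0, 4.5]), min_size=1, max_size=7),
    seed=st.integers(0, 10_000),
)
@settings(deadline=None, derandomize=True, max_examples=60)
def test_km_agrees_with_oracle_on_random_inputs(times, seed):
    rng = np.random.default_rng(seed)
    events = rng.random(len(times)) < 0.6
    grid = np.arange(6)
    curve = d.kaplan_meier(times, events, grid)
    assert np.allclose(curve.S, km_oracle(times, events, grid), atol=1e-12)


def test_logrank_identical_groups():
    t = [1.0, 2.0, 3.0]
    e = [True, True, False]
    stat, p = d.logrank_test(t, e, t, e)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_hand_case():
    """A={death at 1}, B={death at 2}: O-E=0.5, Var=0.25 -> chi2=1, p=0.317."""
    stat, p = d.logrank_test([1.0], [True], [2.0], [True])
    assert stat == pytest.approx(1.0, rel=1e-9)
    assert p == pytest.approx(stats.chi2.sf(1.0, 1), rel=1e-9)


def test_logrank_power_on_separated_hazards():
    rng = np.random.default_rng(1)
    t1 = rng.exponential(1 / 0.02, 500)
    t2 = rng.exponential(1 / 0.05, 500)
    stat, p = d.logrank_test(t1, np.ones(500, bool), t2, np.ones(500, bool))
    assert p < 0.001


def test_logrank_empty_group_rejected():
    with pytest.raises(ValueError):
        d.logrank_test([], [], [1.0], [True])


def test_reference_survival_single_profile(life_table):
    prof = pd.DataFrame({"age_at_index": [60.0] * 5, "sex": ["F"] * 5})
    ref = d.reference_survival(prof, life_table, horizon=240)
    assert np.allclose(ref.S, life_table.survival_path(60.0, "F", 240))


def test_reference_survival_zero_hazard():
    lt = d.build_life_table({"M": d.GompertzParams(0, 0), "F": d.GompertzParams(0, 0)})
    prof = pd.DataFrame({"age_at_index": [40.0, 70.0], "sex": ["M", "F"]})
    ref = d.reference_survival(prof, lt, horizon=120)
    assert np.allclose(ref.S, 1.0)


def test_reference_survival_linearity(life_table):
    a = pd.DataFrame({"age_at_index": [50.0] * 4, "sex": ["M"] * 4})
    b = pd.DataFrame({"age_at_index": [70.0] * 4, "sex": ["F"] * 4})
    both = pd.concat([a, b], ignore_index=True)
    Sa = d.reference_survival(a, life_table, 120).S
    Sb = d.reference_survival(b, life_table, 120).S
    Sab = d.reference_survival(both, life_table, 120).S
    assert np.allclose(Sab, (Sa + Sb) / 2)


def test_reference_survival_monte_carlo_mode(life_table):
    prof = pd.DataFrame({"age_at_index": [65.0] * 200, "sex": ["M"] * 200})
    det = d.reference_survival(prof, life_table, 240)
    mc = d.reference_survival(prof, life_table, 240, monte_carlo=True, n_replicates=50, seed=3)
    assert np.abs(det.S - mc.S).max() < 0.05
    mc2 = d.reference_survival(prof, life_table, 240, monte_carlo=True, n_replicates=50, seed=3)
    assert np.allclose(mc.S, mc2.S)


def _km_equals_ref_fit(life_table, transform):
    prof = pd.DataFrame({"age_at_index": [60.0] * 10, "sex": ["M"] * 10})
    ref = d.reference_survival(prof, life_table, horizon=720)
    km = d.SurvivalCurve(grid=np.arange(169), S=ref.S[:169])
    return d.extrapolate_survival(km, ref, horizon=720, transform=transform)


@pytest.mark.parametrize("transform", ["log", "logit"])
def test_null_excess_recovers_reference(life_table, transform):
    fit = _km_equals_ref_fit(life_table, transform)
    assert abs(fit.slope) < 1e-4
    tail = slice(169, 721)
    ref = d.reference_survival(
        pd.DataFrame({"age_at_index": [60.0] * 10, "sex": ["M"] * 10}), life_table, 720
    )
    assert np.abs(fit.curve.S[tail] - ref.S[tail]).max() < 0.01


def test_extrapolated_curve_below_reference(life_table):
    """With W <= 1 and a nonpositive fitted slope the lifetime curve stays under the reference."""
    cfg = clean_config(n_subjects=1500, seed=31, excess_hazard={"HD": 0.005, "PD": 0.005})
    coh = d.synthetic.generate_subjects(cfg, life_table)
    km = d.kaplan_meier(coh["time"], coh["event"] == "death", np.arange(169))
    ref = d.reference_survival(coh, life_table, 720)
    fit = d.extrapolate_survival(km, ref, 720)
    assert fit.slope <= 0
    assert (fit.curve.S <= ref.S + 1e-9).all()


def test_extrapolation_monotone_in_excess_hazard(life_table):
    les = []
    for lam in (0.002, 0.005, 0.01):
        cfg = clean_config(n_subjects=1500, seed=77, excess_hazard={"HD": lam, "PD": lam})
        coh = d.synthetic.generate_subjects(cfg, life_table)
        km = d.kaplan_meier(coh["time"], coh["event"] == "death", np.arange(169))
        ref = d.reference_survival(coh, life_table, 720)
        fit = d.extrapolate_survival(km, ref, 720)
        les.append(d.restricted_mean(fit.curve, 720))
    assert les[0] > les[1] > les[2]


def test_extrapolation_horizon_bound(life_table):
    fit = _km_equals_ref_fit(life_table, "log")
    assert d.restricted_mean(fit.curve, 720) <= 60.0


def test_extrapolation_error_cases(life_table):
    prof = pd.DataFrame({"age_at_index": [60.0] * 5, "sex": ["M"] * 5})
    ref = d.reference_survival(prof, life_table, 720)
    km = d.SurvivalCurve(grid=np.arange(169), S=ref.S[:169])
    with pytest.raises(ValueError, match="fit window"):
        d.extrapolate_survival(km, ref, 720, fit_window=(160, 164))
    with pytest.raises(ValueError, match="24 months"):
        d.extrapolate_survival(
            d.SurvivalCurve(grid=np.arange(13), S=ref.S[:13]), ref, 720
        )
    dead_ref = d.SurvivalCurve(grid=np.arange(721), S=np.concatenate([[1.0], np.zeros(720)]))
    with pytest.raises(ValueError, match="reaches 0"):
        d.extrapolate_survival(km, dead_ref, 720)
    with pytest.raises(ValueError, match="transform"):
        d.extrapolate_survival(km, ref, 720, transform="loglog")


def test_restricted_mean_closed_forms():
    full = d.SurvivalCurve(grid=np.arange(721), S=np.ones(721))
    assert d.restricted_mean(full, 720) == pytest.approx(60.0)
    geo = d.SurvivalCurve(grid=np.arange(721), S=0.99 ** np.arange(721))
    expected = 0.99 * (1 - 0.99**720) / 0.01 / 12
    assert d.restricted_mean(geo, 720) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(8.244, abs=5e-3)
    dead = d.SurvivalCurve(grid=np.arange(3), S=[1.0, 0.0, 0.0])
    assert d.restricted_mean(dead, 2) == 0.0
    with pytest.raises(ValueError):
        d.restricted_mean(dead, 10)


def test_bootstrap_constant_statistic_zero_se():
    se, _ = d.bootstrap_se(pd.DataFrame({"x": range(30)}), lambda df: 1.0, B=20, seed=0)
    assert se == 0.0


def test_bootstrap_se_of_mean_matches_closed_form():
    rng = np.random.default_rng(8)
    data = pd.DataFrame({"x": rng.normal(0.0, 1.0, 100)})
    se, ci = d.bootstrap_se(data, lambda df: df["x"].mean(), B=200, seed=1)
    assert abs(se - 0.1) < 0.03  # sigma/sqrt(n) = 0.1
    assert ci[0] < data["x"].mean() < ci[1]


def test_bootstrap_deterministic_and_validated():
    data = pd.DataFrame({"x": np.arange(50.0)})
    se1, _ = d.bootstrap_se(data, lambda df: df["x"].mean(), B=50, seed=9)
    se2, _ = d.bootstrap_se(data, lambda df: df["x"].mean(), B=50, seed=9)
    assert se1 == se2
    with pytest.raises(ValueError):
        d.bootstrap_se(data, lambda df: 0.0, B=1)


def test_survival_curve_invariants_enforced():
    with pytest.raises(ValueError):
        d.SurvivalCurve(grid=np.arange(3), S=[1.0, 0.5, 0.6])  # increasing
    with pytest.raises(ValueError):
        d.SurvivalCurve(grid=np.arange(2), S=[0.9, 0.5])  # S(0) != 1
    with pytest.raises(ValueError):
        d.SurvivalCurve(grid=np.array([1, 2]), S=[1.0, 0.5])  # grid not from 0
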