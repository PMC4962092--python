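import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dialcea as d
from dialcea.config import CostParams
from conftest import clean_config


def _records(rows):
    return pd.DataFrame(rows, columns=["id", "month", "outpatient", "inpatient", "year"])


def test_cpi_adjustment():
    rec = _records([(0, 1, 100.0, 0.0, 2005), (0, 2, 100.0, 50.0, 2010)])
    cpi = {2005: 95.0, 2010: 100.0}
    adj = d.cpi_adjust(rec, cpi, base_year=2010)
    assert adj.loc[0, "outpatient"] == pytest.approx(100 * 100 / 95)
    assert adj.loc[0, "outpatient"] == pytest.approx(105.26, abs=0.01)
    assert adj.loc[1, "outpatient"] == 100.0  # base-year record unchanged
    flat = d.cpi_adjust(rec, {2005: 100.0, 2010: 100.0}, 2010)
    pd.testing.assert_frame_equal(flat, rec)
    with pytest.raises(ValueError, match="lacks calendar years"):
        d.cpi_adjust(rec, {2010: 100.0}, 2010)
    with pytest.raises(ValueError, match="base year"):
        d.cpi_adjust(rec, {2005: 95.0, 2010: 100.0}, 1990)


def test_mean_monthly_cost():
    rec = _records(
        [(0, 5, 0.0, 0.0, 2010), (1, 5, 2000.0, 0.0, 2010), (0, 6, 800.0, 100.0, 2010)]
    )
    curve = d.mean_monthly_cost(rec)
    assert curve.total[curve.grid == 5][0] == pytest.approx(1000.0)
    assert curve.total[curve.grid == 6][0] == pytest.approx(900.0)
    single = d.mean_monthly_cost(_records([(0, m, 1000.0, 0.0, 2010) for m in range(1, 13)]))
    assert np.allclose(single.total, 1000.0)
    assert np.allclose(curve.total, curve.inpatient + curve.outpatient)


def test_extend_cost_carries_recent_mean():
    curve = d.CostCurve(
        grid=np.arange(1, 25),
        inpatient=np.zeros(24),
        outpatient=np.concatenate([np.full(12, 500.0), np.full(12, 1000.0)]),
    )
    ext = d.extend_cost(curve, 36, carry_window=12)
    assert np.allclose(ext.outpatient[24:], 1000.0)
    ext6 = d.extend_cost(curve, 36, carry_window=24)
    assert np.allclose(ext6.outpatient[24:], 750.0)


def test_discount_factors():
    cfg = d.CEAConfig(discount_rate=0.03, discount_start_month=168, cpi={2010: 100})
    grid = np.arange(1, 721)
    f = d.discount_factors(grid, cfg)
    assert np.allclose(f[grid <= 168], 1.0)
    assert f[grid == 168 + 24][0] == pytest.approx(1.03 ** -2)
    assert f[grid == 168 + 1][0] == pytest.approx(1.03 ** -1)
    assert (np.diff(f) <= 1e-15).all()
    zero = d.discount_factors(grid, d.CEAConfig(discount_rate=0.0, cpi={2010: 100}))
    assert np.allclose(zero, 1.0)
    with pytest.raises(ValueError):
        d.CEAConfig(discount_rate=-0.01)


def test_lifetime_cost_closed_forms():
    grid = np.arange(721)
    ones = d.SurvivalCurve(grid=np.arange(13), S=np.ones(13))
    cost12 = d.CostCurve(grid=np.arange(1, 13), inpatient=np.zeros(12), outpatient=np.ones(12))
    assert d.lifetime_cost(ones, cost12, np.ones(12), 12) == pytest.approx(12.0)

    geo = d.SurvivalCurve(grid=grid, S=0.99 ** grid)
    c = d.CostCurve(grid=np.arange(1, 721), inpatient=np.zeros(720), outpatient=np.full(720, 1000.0))
    total = d.lifetime_cost(geo, c, np.ones(720), 720)
    assert total == pytest.approx(1000 * 0.99 * (1 - 0.99**720) / 0.01, rel=1e-12)
    assert total == pytest.approx(98_928.8, abs=1.0)
    doubled = d.CostCurve(grid=np.arange(1, 721), inpatient=np.zeros(720), outpatient=np.full(720, 2000.0))
    assert d.lifetime_cost(geo, doubled, np.ones(720), 720) == pytest.approx(2 * total)


def test_qale_identities():
    grid = np.arange(721)
    S = np.exp(-0.004 * grid)
    surv = d.SurvivalCurve(grid=grid, S=S)
    le = d.restricted_mean(surv, 720)
    u1 = d.UtilityCurve(grid=grid, u=np.ones(721), k=50)
    uhalf = d.UtilityCurve(grid=grid, u=np.full(721, 0.5), k=50)
    ones = np.ones(720)
    assert d.qale(surv, u1, ones, 720) == pytest.approx(le, rel=1e-12)
    assert d.qale(surv, uhalf, ones, 720) == pytest.approx(le / 2, rel=1e-12)
    disc = d.discount_factors(np.arange(1, 721), d.CEAConfig(discount_rate=0.03, cpi={}))
    assert d.qale(surv, u1, disc, 720) < le


def test_grid_mismatch_rejected():
    surv = d.SurvivalCurve(grid=np.arange(13), S=np.ones(13))
    short_cost = d.CostCurve(grid=np.arange(1, 7), inpatient=np.zeros(6), outpatient=np.ones(6))
    with pytest.raises(ValueError):
        d.lifetime_cost(surv, short_cost, np.ones(12), 12)


def test_cost_per_qaly_printed_values():
    assert d.cost_per_qaly(237_795, 14.29) == pytest.approx(16_643, rel=1e-3)
    assert d.cost_per_qaly(204_442, 14.94) == pytest.approx(13_681, rel=1e-3)
    assert d.cost_per_qaly(0.0, 10.0) == 0.0
    with pytest.raises(ValueError):
        d.cost_per_qaly(1000.0, 0.0)


def test_icer_dominance_logic():
    res = d.icer(204_442, 14.94, 237_795, 14.29)
    assert res.flag == "a dominant"
    assert res.icer < 0
    assert res.icer == pytest.approx((204_442 - 237_795) / 0.65, rel=1e-12)

    tie = d.icer(100.0, 10.0, 200.0, 10.0)
    assert tie.flag == "a cost-dominant"
    assert math.isnan(tie.icer)
    assert tie.cost_diff == -100.0

    assert d.icer(100.0, 12.0, 90.0, 10.0).flag == "tradeoff"
    assert d.icer(90.0, 9.0, 100.0, 10.0).flag == "tradeoff"
    assert d.icer(100.0, 9.0, 90.0, 10.0).flag == "b dominant"
    assert d.icer(50.0, 10.0, 50.0, 10.0).flag == "equivalent"


def test_gdp_fold():
    assert d.gdp_fold(13_681, 18_573) == 0.74
    assert d.gdp_fold(16_643, 18_573) == 0.90
    assert d.gdp_fold(18_573, 18_573) == 1.00
    with pytest.raises(ValueError):
        d.gdp_fold(1000.0, 0.0)


@given(rate=st.floats(0.0, 0.2), start=st.integers(0, 240))
@settings(deadline=None, derandomize=True, max_examples=40)
def test_discount_factors_monotone_property(rate, start):
    cfg = d.CEAConfig(discount_rate=rate, discount_start_month=start, cpi={})
    f = d.discount_factors(np.arange(1, 400), cfg)
    assert (f <= 1.0 + 1e-15).all() and (f > 0).all()
    assert (np.diff(f) <= 1e-15).all()


def test_constant_hazard_constant_cost_closed_form(flat_life_table):
    """Flat hazards, constant cost c and utility u, no discounting:
    lifetime cost -> c * 12 * LE and QALE -> u * LE."""
    lam = 0.003
    cfg = clean_config(
        n_subjects=3000, seed=19, excess_hazard={"HD": lam, "PD": lam},
        cost=CostParams(
            outpatient_mean={"HD": 1000.0, "PD": 1000.0},
            inpatient_event_rate=0.0, first_month_multiplier=1.0, noise_cv=0.0,
        ),
    )
    coh = d.synthetic.generate_subjects(cfg, flat_life_table)
    km = d.kaplan_meier(coh["time"], coh["event"] == "death", np.arange(169))
    ref = d.reference_survival(coh, flat_life_table, 720)
    fit = d.extrapolate_survival(km, ref, 720)
    le = d.restricted_mean(fit.curve, 720)

    costs = d.synthetic.generate_cost_streams(coh, cfg)
    curve = d.extend_cost(d.mean_monthly_cost(costs), 720)
    ones = np.ones(720)
    total = d.lifetime_cost(fit.curve, curve, ones, 720)
    assert total == pytest.approx(1000.0 * 12 * le, rel=0.02)

    u = d.UtilityCurve(grid=np.arange(721), u=np.full(721, 0.7), k=50)
    assert d.qale(fit.curve, u, ones, 720) == pytest.approx(0.7 * le, rel=0.02)
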