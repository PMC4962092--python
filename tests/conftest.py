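import numpy as np
import pytest

import dialcea as d


@pytest.fixture(scope="session")
def life_table() -> d.LifeTable:
    """Gompertz reference mortality: monthly hazard a*exp(b*age), mildly sex-split."""
    return d.build_life_table(
        {"M": d.GompertzParams(7e-6, 0.085), "F": d.GompertzParams(5e-6, 0.085)}
    )


@pytest.fixture(scope="session")
def flat_life_table() -> d.LifeTable:
    """Age-independent background mortality (b=0), handy for closed forms."""
    return d.build_life_table(
        {"M": d.GompertzParams(1e-4, 0.0), "F": d.GompertzParams(1e-4, 0.0)}
    )


@pytest.fixture(scope="session")
def uk_vs() -> d.ValueSet:
    return d.uk_tariff()


@pytest.fixture
def small_config() -> d.SimulationConfig:
    return d.SimulationConfig(n_subjects=600, seed=7)


def clean_config(**kw) -> d.SimulationConfig:
    """Config without planted ineligible subjects (pure survival/cost studies)."""
    from dialcea.config import IneligibleFractions

    kw.setdefault("ineligible", IneligibleFractions(0, 0, 0, 0, 0, 0))
    return d.SimulationConfig(**kw)


def km_oracle(times, events, grid) -> np.ndarray:
    """Brute-force product-limit estimator (deaths precede censorings at ties)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    death_times = np.unique(times[events])
    out = []
    for t in np.asarray(grid):
        s = 1.0
        for dt in death_times:
            if dt <= t:
                at_risk = (times >= dt).sum()
                deaths = ((times == dt) & events).sum()
                s *= 1.0 - deaths / at_risk
        out.append(s)
    return np.array(out)
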