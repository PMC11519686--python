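import numpy as np
import pytest

import previts as pv


@pytest.fixture(scope="session")
def default_design():
    """Lagged design matrix for the built-in 11-event calendar, 217 weeks."""
    return pv.build_design_matrix()


@pytest.fixture(scope="session")
def noisy_series_and_design():
    """One simulated ARIMA(0,1,1) ITS series with a known injected effect."""
    sc = pv.Scenario(
        drift=0.034, innovation_sd=0.5, ma_theta=0.5, d=1,
        effects={4: -0.93}, seed=20240217,
    )
    return pv.simulate_weekly_series(sc), sc.design(), sc


@pytest.fixture(scope="session")
def small_microdata():
    """Microdata tracking a short constant 40% target series."""
    target = pv.WeeklySeries(np.full(8, 40.0))
    msc = pv.MicrodataScenario(respondents_per_week=200, missing_rate=0.05, seed=7)
    return pv.simulate_microdata(msc, target), target
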