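import numpy as np
import pandas as pd
import pytest

from heatmort.synthetic_world import WorldConfig, simulate_community


@pytest.fixture(scope="session")
def small_world():
    """A small but complete synthetic world shared across tests."""
    from heatmort.synthetic_world import generate_world

    cfg = WorldConfig(
        n_communities=6,
        years_observed=12,
        n_countries=3,
        n_gcms=3,
        rcp_warming={"rcp45": 0.25, "rcp85": 0.5},
        seed=2024,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def fitted_community():
    """One community's records together with its stage-1 fit."""
    from heatmort.heatwave_calendar import determine_hot_season
    from heatmort.stage1_dlnm import fit_first_stage

    cfg = WorldConfig(
        n_communities=1,
        years_observed=15,
        true_log_rr_cumulative=float(np.log(1.25)),
        seed=424242,
    )
    records, thr = simulate_community(cfg)
    season = determine_hot_season(records["temperature"])
    fit = fit_first_stage(records, season, community="c0")
    return cfg, records, thr, season, fit


def brute_force_heatwave_indicator(temps, threshold, min_duration=2):
    """Independent O(n) run-length oracle used to validate detection."""
    n = len(temps)
    ind = np.zeros(n, dtype=int)
    run = 0
    for i in range(n + 1):
        exceed = (
            i < n and np.isfinite(temps[i]) and temps[i] > threshold
        )
        if exceed:
            run += 1
        else:
            if run >= min_duration:
                ind[i - run: i] = 1
            run = 0
    return ind


@pytest.fixture
def brute_force_oracle():
    return brute_force_heatwave_indicator


def daily_index(start="2001-01-01", years=10):
    end_year = pd.Timestamp(start).year + years - 1
    return pd.date_range(start, f"{end_year}-12-31", freq="D")
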