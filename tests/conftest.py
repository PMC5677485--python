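import warnings

import numpy as np
import pandas as pd
import pytest

from sdm_uncertainty.synthetic_world import (
    WorldConfig,
    generate_climate,
    generate_occurrences,
    perturb_gcm,
)


@pytest.fixture(scope="session")
def world_config() -> WorldConfig:
    """Small but structurally full world: 39 years, 7 drought years."""
    return WorldConfig(n_sites=25, n_years=39, n_species=3, n_gcms=3, seed=7)


@pytest.fixture(scope="session")
def observed_panel(world_config):
    return generate_climate(world_config)


@pytest.fixture(scope="session")
def full_panel(world_config, observed_panel):
    return perturb_gcm(observed_panel, world_config)


@pytest.fixture(scope="session")
def occurrences(world_config, observed_panel):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_occurrences(observed_panel, world_config)


def toy_panel(monthly_temp, monthly_precip, n_years=1, site=0):
    """A single-site observed panel from explicit 12-month sequences."""
    temp = np.asarray(monthly_temp, dtype=float)
    precip = np.asarray(monthly_precip, dtype=float)
    rows = []
    for y in range(n_years):
        for m in range(12):
            rows.append(
                {
                    "site": site,
                    "year": 2000 + y,
                    "month": m + 1,
                    "temperature": temp[y % temp.shape[0]][m] if temp.ndim == 2 else temp[m],
                    "precipitation": precip[y % precip.shape[0]][m]
                    if precip.ndim == 2
                    else precip[m],
                    "scenario": "observed",
                    "member": "obs",
                }
            )
    return pd.DataFrame(rows)
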