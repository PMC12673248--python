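import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import phenosync as ps

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")
import phenosync.records as rp


@pytest.fixture(scope="session")
def small_population():
    """One small synthetic birth-record dataset with its truth ledger."""
    scen = ps.small_scenario()
    records, truth = ps.gen_population(scen, seed=42)
    return records, truth


@pytest.fixture(scope="session")
def model_table(small_population):
    """Censored, covariate-attached model table for the small dataset."""
    records, truth = small_population
    table, consts = rp.attach_covariates(
        rp.censor_records(records),
        records[["region_id"]].drop_duplicates(),
        covariate_columns=["elevation", "latitude"] + list(ps.COLWELL_COVARIATES),
    )
    return table, consts, truth


@pytest.fixture(scope="session")
def daily_series():
    """Two full years of daily timestamps."""
    return pd.date_range("2001-01-01", "2002-12-31", freq="D")


def make_series(dates, values, variable="temperature", site="s1"):
    return pd.DataFrame(
        {"site_id": site, "date": dates, "variable": variable,
         "value": np.asarray(values, dtype=float)}
    )
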