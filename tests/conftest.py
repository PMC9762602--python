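import numpy as np
import pandas as pd
import pytest

from bcaisd.cohort_sim import CohortTable, FeatureMeta, GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-size cohort under the default study conditions."""
    return generate_cohort(GeneratorConfig(n=2000, seed=42))


@pytest.fixture(scope="session")
def clean_cohort():
    """No missingness — ready for direct encoding."""
    cfg = GeneratorConfig(n=2000, seed=43, item_missing_rate=0.0,
                          block_missing_rates={})
    return generate_cohort(cfg)


def make_numeric_table(columns: dict, time=None, event=None, lo=-1e6, hi=1e6):
    """Small all-numeric CohortTable from raw column arrays."""
    n = len(next(iter(columns.values())))
    meta = [FeatureMeta(c, "HLQ", "numeric", True, (lo, hi)) for c in columns]
    df = pd.DataFrame({"id": np.arange(n),
                       "time_months": np.ones(n) if time is None else np.asarray(time, float),
                       "event": np.zeros(n, int) if event is None else np.asarray(event, int)})
    for c, v in columns.items():
        df[c] = np.asarray(v, float)
    return CohortTable(df, meta)


@pytest.fixture
def numeric_table_factory():
    return make_numeric_table
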