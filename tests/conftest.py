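import numpy as np
import pandas as pd
import pytest

from pcssreg import SummarySet


def summarize_df(df, cohort="", stratum=""):
    """Brute-force summary of a row-level table (the concatenation oracle)."""
    return SummarySet.from_dataframe(df, cohort, stratum)


@pytest.fixture
def toy_cohorts():
    """Two small listed-row cohorts over the same two variables."""
    a = pd.DataFrame({"x": [1.0, 2.0, 4.0], "y": [0.5, 1.5, 1.0]})
    b = pd.DataFrame({"x": [3.0, 5.0, 2.0, 7.0], "y": [2.0, 0.0, 1.0, 3.0]})
    return {"A": a, "B": b}


@pytest.fixture
def toy_sets(toy_cohorts):
    return [summarize_df(df, lab) for lab, df in toy_cohorts.items()]


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
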