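import io

import numpy as np
import pandas as pd
import pytest

import twinace as tw


@pytest.fixture
def tiny_csv(tmp_path):
    """Two MZF twins in one family, one measure, one missing value."""
    text = (
        "family_id,zygosity,sex,birth_order,age,bmi\n"
        "F001,MZF,female,1,42.5,23.1\n"
        "F001,MZF,female,2,42.5,\n"
    )
    p = tmp_path / "tiny.csv"
    p.write_text(text)
    return p


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort under the default generating conditions."""
    return tw.simulate(tw.SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort_config():
    return tw.SimConfig(seed=11)


def make_dataset(rows, measures=("y",)):
    """Build a TwinDataset from (family, zygosity, sex, order, age, *values) tuples."""
    cols = ["family_id", "zygosity", "sex", "birth_order", "age", *measures]
    df = pd.DataFrame(rows, columns=cols)
    return tw.TwinDataset(df, list(measures))
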