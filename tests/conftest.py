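import numpy as np
import pandas as pd
import pytest

from herbqc import datasets, rsm


@pytest.fixture(scope="session")
def bbd_table() -> pd.DataFrame:
    return datasets.load_bbd_table()


@pytest.fixture(scope="session")
def compound_table() -> pd.DataFrame:
    return datasets.load_compound_table()


@pytest.fixture(scope="session")
def plasma_table() -> pd.DataFrame:
    return datasets.load_plasma_table()


@pytest.fixture(scope="session")
def fitted_extraction_model(bbd_table):
    """The quadratic desirability model fitted to the 17-run design."""
    design, responses = rsm.read_run_table(bbd_table)
    return rsm.fit_quadratic(design, responses["OD"].to_numpy())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
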