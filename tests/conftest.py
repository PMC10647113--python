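import numpy as np
import pandas as pd
import pytest

import hsekit as hk


@pytest.fixture(scope="session")
def fixture_panel():
    return hk.load_efficiency_fixture()


@pytest.fixture(scope="session")
def china_weights():
    return hk.build_weights(hk.load_china_adjacency(), style="row_standardized")


@pytest.fixture(scope="session")
def small_synthetic():
    truth = hk.FrontierTruth(n_units=8, n_periods=4, seed=11)
    panel, u, te = hk.generate_panel(truth)
    return truth, panel, u, te


def panel_from_eps(eps, start_year=2000):
    """Wrap a units x periods residual matrix as a panel with zero regressors.

    With beta = 0 the model residuals equal ln_output_index, so likelihood
    oracles can be evaluated on an arbitrary eps matrix through the public
    API.
    """
    n, T = eps.shape
    units = [f"U{i}" for i in range(n)]
    years = list(range(start_year, start_year + T))
    df = pd.DataFrame({
        "unit_id": np.repeat(units, T),
        "region": "synthetic",
        "year": np.tile(years, n),
        "ln_labor": 0.0,
        "ln_capital": 0.0,
        "ln_output_index": np.asarray(eps, dtype=float).ravel(),
    })
    return hk.ProvincePanel(df)
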