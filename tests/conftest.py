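import numpy as np
import pytest

import ccbiophys as cc


@pytest.fixture(scope="session")
def ramp_temps():
    """Standard melt temperature grid: 10-105 degC in 1 degC steps."""
    return np.arange(10.0, 105.0 + 1e-9, 1.0)


@pytest.fixture(scope="session")
def wt_faruv_model():
    """Three-state model with the wild-type far-UV CD transitions."""
    return cc.UnfoldingModelParams(3, [(55.5, 300.0), (87.1, 500.0)])
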