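import numpy as np
import pandas as pd
import pytest

from spotval import calibration as cal
from spotval import simulate as sim
from spotval.panel import default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def reference_truth():
    """Panel-wide generative truth mirroring the packaged reference fixture."""
    return sim.default_truth_panel(base_cv=0.08)


@pytest.fixture
def pfba_truth():
    return sim.AnalyteTruth(order="linear", a1=0.8092, a0=0.0579, variance_power=2.0, base_cv=0.08)


@pytest.fixture
def clean_linear_frame():
    """Noise-free 6x3x3 calibration records on y = 0.9x (a0 = 0)."""
    truth = sim.AnalyteTruth(order="linear", a1=0.9, a0=0.0, base_cv=0.0)
    config = sim.SyntheticConfig(truth={"A1": truth}, seed=0)
    return sim.generate_calibration(config)


@pytest.fixture
def noisy_frame(pfba_truth):
    config = sim.SyntheticConfig(truth={"PFBA": pfba_truth}, seed=11)
    return sim.generate_calibration(config)


def ratio_xy(frame, is_conc=20.0):
    return cal.ratio_data(frame, is_conc)


@pytest.fixture(scope="session")
def wls_oracle():
    """Brute-force weighted normal equations: beta = (X'WX)^-1 X'Wy."""

    def fit(x, y, w, degree):
        X = np.vander(np.asarray(x, float), degree + 1, increasing=True)
        W = np.diag(np.asarray(w, float))
        return np.linalg.solve(X.T @ W @ X, X.T @ W @ np.asarray(y, float))

    return fit
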