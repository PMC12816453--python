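import numpy as np
import pytest

from cestpipe.lorentz import aptw_config
from cestpipe.zspec import cest_axis, wassr_axis

# ground-truth APTw five-pool parameters used across recovery tests:
# amplitudes / centers (ppm) / widths (ppm) for water, amide, amine, MT, NOE
APTW_TRUTH = {
    "amplitudes": np.array([0.85, 0.05, 0.03, 0.10, 0.08]),
    "centers": np.array([0.0, 3.5, 2.2, -2.0, -3.5]),
    "widths": np.array([1.4, 1.0, 1.5, 6.0, 3.0]),
    "z_base": 1.0,
}


@pytest.fixture(scope="session")
def axis():
    return cest_axis()


@pytest.fixture(scope="session")
def waxis():
    return wassr_axis()


@pytest.fixture(scope="session")
def aptw():
    return aptw_config()


@pytest.fixture(scope="session")
def aptw_truth():
    return APTW_TRUTH


@pytest.fixture(scope="session")
def aptw_spectrum(axis, aptw_truth):
    """Noiseless five-pool APTw z-spectrum on the 0.1 ppm grid."""
    from cestpipe.lorentz import model_eval
    return model_eval(aptw_truth["amplitudes"], aptw_truth["centers"],
                      aptw_truth["widths"], aptw_truth["z_base"], axis)
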