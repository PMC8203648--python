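import numpy as np
import pytest

from stimfc import HRFParams, build_costim_paradigm
from stimfc.preprocess import VolumeSeries


@pytest.fixture
def hrf() -> HRFParams:
    return HRFParams()


@pytest.fixture
def costim_paradigm():
    """The default co-stimulation protocol: 16 heat-class stimuli at a
    100 s interval, every 2nd combined with laser, interleaved lasers."""
    return build_costim_paradigm()


@pytest.fixture
def short_paradigm():
    """Desk-scale protocol: 4 heat-class events in 250 volumes."""
    return build_costim_paradigm(n_heat=4, n_volumes=250)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def make_series(data: np.ndarray, tr: float = 4.0) -> VolumeSeries:
    return VolumeSeries(data=np.asarray(data, dtype=float), tr=tr)


@pytest.fixture
def noise_series(rng) -> VolumeSeries:
    return make_series(rng.standard_normal((4, 4, 2, 200)) + 100.0)
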