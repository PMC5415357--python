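import numpy as np
import pytest

from axatp.imaging import NormalizedSeries
from axatp.presets import preset
from axatp.simulate import simulate_experiment


@pytest.fixture(scope="session")
def mbgd_noiseless():
    """One noiseless MB+GD experiment (baseline, 5 min depletion, recovery)."""
    return simulate_experiment(preset("MBGD", noiseless=True))


@pytest.fixture(scope="session")
def mbgd_noisy():
    return simulate_experiment(preset("MBGD", seed=7))


@pytest.fixture(scope="session")
def hfs100_noiseless():
    return simulate_experiment(preset("HFS100@glc10", noiseless=True))


@pytest.fixture(scope="session")
def gd_noiseless():
    return simulate_experiment(preset("GD", noiseless=True))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_series(time_s, value, kind="ATP", **kw):
    return NormalizedSeries(time_s=np.asarray(time_s, float),
                            value=np.asarray(value, float), kind=kind, **kw)
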