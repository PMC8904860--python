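import numpy as np
import pytest

from xenotrial.simdata import SimConfig
from xenotrial.trial import VolumeMeasurement


def vm(day: float, volume: float) -> VolumeMeasurement:
    """Measurement with equal caliper axes realizing a target volume."""
    w = float(np.cbrt(2.0 * volume))
    return VolumeMeasurement(day=day, width=w, length=w)


@pytest.fixture
def low_noise_config() -> SimConfig:
    return SimConfig(n_cases=6, measurement_cv=0.02, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
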