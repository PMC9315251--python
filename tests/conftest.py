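import numpy as np
import pytest

from hydropulse import (
    NBR_MEMBRANE,
    STEEL_PROJECTILE,
    STEEL_TUBE,
    WATER,
    ExperimentConfig,
    SourcePulse,
)
from hydropulse import physics


@pytest.fixture(scope="session")
def water():
    return WATER


@pytest.fixture(scope="session")
def steel_tube():
    return STEEL_TUBE


@pytest.fixture(scope="session")
def projectile():
    return STEEL_PROJECTILE


@pytest.fixture(scope="session")
def membrane():
    return NBR_MEMBRANE


@pytest.fixture(scope="session")
def default_config():
    return ExperimentConfig()


@pytest.fixture(scope="session")
def default_pulse(default_config):
    return default_config.source_pulse()


@pytest.fixture
def short_pulse():
    """Fast-decaying pulse so multi-arrival tests separate cleanly in time."""
    return SourcePulse(peak_pressure=1e6, decay_constant=5e-6, onset_time=0.0)


@pytest.fixture(scope="session")
def korteweg_default(water, steel_tube):
    return physics.korteweg_celerity(water, steel_tube)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
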