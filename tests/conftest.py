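import numpy as np
import pytest

from gaugebp.simulate import (
    AdcModel,
    ContactPressureProfile,
    Harmonic,
    PulseWaveModel,
    TissueModel,
)


@pytest.fixture
def two_harmonic_pulse() -> PulseWaveModel:
    """Canonical resting pulse: MAP 100, 1.2 Hz fundamental + first overtone."""
    return PulseWaveModel(
        mean_pressure=100.0,
        harmonics=(Harmonic(20.0, 1.2), Harmonic(8.0, 2.4)),
    )


@pytest.fixture
def wrist_tissue() -> TissueModel:
    return TissueModel(alpha=4.5)


@pytest.fixture
def quiet_contact() -> ContactPressureProfile:
    return ContactPressureProfile(baseline=40.0, noise_sd=0.0)


@pytest.fixture
def adc() -> AdcModel:
    return AdcModel()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
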