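import numpy as np
import pytest

from multispec.spectral import SpectralCurve
from multispec.synth import (
    avian_receptors,
    daylight_illuminant,
    default_camera,
    generate_spectra_library,
)


@pytest.fixture(scope="session")
def illuminant():
    return daylight_illuminant()


@pytest.fixture(scope="session")
def camera(illuminant):
    return default_camera(illuminant)


@pytest.fixture(scope="session")
def receptors():
    return avian_receptors()


@pytest.fixture(scope="session")
def small_library():
    return generate_spectra_library(60, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def flat_curve(level: float, start=300, end=700, name="flat") -> SpectralCurve:
    return SpectralCurve(start, np.full(end - start + 1, level), name=name)
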