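import numpy as np
import pytest

from besselflow import (
    AcquisitionParams,
    BeamParameters,
    ObjectSpec,
    ScenePlan,
    comb_weights,
    synthesize_waveform,
)


@pytest.fixture(scope="session")
def beam():
    return BeamParameters()


@pytest.fixture(scope="session")
def comb(beam):
    return comb_weights(beam)


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def acq_quiet():
    """Acquisition with noise and background ripple off, for exact checks."""
    return AcquisitionParams(noise_sigma=0.0, background_amplitude=0.0)


@pytest.fixture(scope="session")
def bead_record_factory(comb):
    """Single centred bead record at chosen diameter/speed, noise off."""

    def _make(diameter=15.0, speed=20.0, noise_sigma=0.0, background=0.0,
              bright_spot=True, seed=0):
        params = AcquisitionParams(
            noise_sigma=noise_sigma, background_amplitude=background
        )
        spec = ObjectSpec(
            kind="bead",
            diameter=diameter,
            speed=speed,
            arrival_time=600.0,
            bright_spot=bright_spot,
        )
        scene = ScenePlan(objects=[spec], seed=seed)
        return synthesize_waveform(scene, comb, params, seed=seed)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
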