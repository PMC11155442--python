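import numpy as np
import pytest

from cervelast import (CompressionProtocol, DepthTrack, ProbeSpec, TissueModel,
                       simulate_exam)

REFERENCE_ELASTICITY = 21.0 / 18.0  # 43 mm -> 25 mm at 21 kPa


@pytest.fixture(scope="session")
def probe():
    return ProbeSpec()


@pytest.fixture(scope="session")
def quiet_tissue():
    """Reference tissue (43 mm, 21/18 kPa/mm) with noise sources disabled."""
    return TissueModel(elasticity_kpa_mm=REFERENCE_ELASTICITY, rest_length_mm=43.0,
                       scatterer_density_per_mm=0.0)


@pytest.fixture(scope="session")
def compression_recording(quiet_tissue, probe):
    """Noise-free compression exam: 1 -> 21 kPa over 3 s at 100 fps."""
    return simulate_exam(quiet_tissue, probe, CompressionProtocol(), seed=0,
                         snr_db=None, pressure_noise=False)


def make_track(depths, pressures, valid=None, c=1540.0):
    depths = np.asarray(depths, dtype=float)
    pressures = np.asarray(pressures, dtype=float)
    valid = np.ones(len(depths), bool) if valid is None else np.asarray(valid, bool)
    return DepthTrack(
        timestamp_s=np.arange(len(depths)) / 100.0,
        pressure_kpa=pressures,
        depth_mm=depths,
        amplitude=np.ones(len(depths)),
        valid=valid,
        speed_of_sound=c,
    )
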