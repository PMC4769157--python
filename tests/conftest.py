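import numpy as np
import pytest
from hypothesis import settings

from nucstep import (ConstructSpec, SimulationParams, default_calibration,
                     get_construct)

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def calibration():
    """FRET = 0.9 - 0.053 * linker_bp over linkers 0-12 bp."""
    return default_calibration()


@pytest.fixture
def end6():
    return get_construct("H2A/[end,+6]")


@pytest.fixture
def quiet_params():
    """Noise-free, bleach-free generator settings."""
    return SimulationParams(noise_sd=0.0, bleach_rate=0.0, seed=0)


def make_staircase(levels, pauses, noise_sd=0.0, rng=None):
    """Piecewise-constant series: levels[i] held for pauses[i] frames.

    Returns (series, change_points) with change points as first frames
    of each new plateau.
    """
    assert len(levels) == len(pauses)
    y = np.repeat(np.asarray(levels, float), np.asarray(pauses, int))
    cps = np.cumsum(pauses)[:-1].tolist()
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        y = y + rng.normal(0.0, noise_sd, y.size)
    return y, cps


@pytest.fixture
def staircase():
    return make_staircase
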