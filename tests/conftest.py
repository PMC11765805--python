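import numpy as np
import pytest

from forkdyn.schedule import ChannelKinetics, KineticSchedule, hu_schedule
from forkdyn.simulate import OpticsNoise, SceneGeometry, random_geometry, render_movie

NOISE_FREE = dict(photon_scale=0.0, read_sigma=0.0)


@pytest.fixture(scope="session")
def stall_schedule():
    """Baseline + 1 h treatment, no washout (the fitting test-bed)."""
    return hu_schedule(washout_min=0.0)


@pytest.fixture(scope="session")
def full_schedule():
    """Baseline + treatment + washout/restart."""
    return hu_schedule(washout_min=45.0)


@pytest.fixture(scope="session")
def small_geometry():
    """A compact nucleus with a handful of foci for fast rendering."""
    return random_geometry(11, shape=(96, 96), n_foci=8)


@pytest.fixture(scope="session")
def noise_free_movie(stall_schedule, small_geometry):
    optics = OpticsNoise(seed=5, **NOISE_FREE)
    return render_movie(stall_schedule, small_geometry, optics)


@pytest.fixture(scope="session")
def noisy_movie(stall_schedule, small_geometry):
    optics = OpticsNoise(seed=5)
    return render_movie(stall_schedule, small_geometry, optics)
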