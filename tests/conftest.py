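import numpy as np
import pytest
from hypothesis import settings

import lymphtrack as lt

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(track_id, xyz, dt=30.0, t0=0.0, frames=None):
    """Build a Track from a position array, optionally on a sparse frame grid."""
    xyz = np.asarray(xyz, dtype=float)
    if frames is None:
        frames = np.arange(len(xyz))
    t = t0 + dt * np.asarray(frames, dtype=float)
    return lt.Track(track_id, t, xyz, dt)


@pytest.fixture(scope="session")
def brownian_population():
    """200 Brownian tracks (D = 10 μm²/min) recorded at 30 s for 60 cycles.

    A roomy volume keeps boundary fragmentation low so the analytic
    6Dτ MSD check is clean.
    """
    vol = lt.ImagingVolume((0.0, 0.0, 0.0), (400.0, 400.0, 300.0))
    cfg = lt.SimulationConfig(n_agents=200, duration=59 * 30.0, volume=vol,
                              placement_margin=20.0, seed=42)
    return lt.simulate(lt.BrownianModel(10.0), cfg), 10.0
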