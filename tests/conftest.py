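import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import houndpath as hp

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def track() -> hp.TrackGeometry:
    """The study track: 40 m straights, 52 m bends measured 1 m out."""
    return hp.default_track()


@pytest.fixture(scope="session")
def noisefree_race(track):
    """One zero-noise race with fixed lane offsets, plus its config."""
    cfg = hp.SimulationConfig(
        rng_seed=42,
        position_noise_sd=0.0,
        sample_rate_jitter=0.0,
        speed_scale_jitter=0.0,
    )
    rec, truth = hp.simulate_race(track, cfg)
    return rec, truth, cfg


@pytest.fixture(scope="session")
def noisy_race(track):
    cfg = hp.SimulationConfig(rng_seed=7)
    rec, truth = hp.simulate_race(track, cfg)
    return rec, truth, cfg


def circle_points(radius: float, angles_deg, centre=(0.0, 0.0)) -> np.ndarray:
    """Concyclic points, counter-clockwise for increasing angles."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return np.stack(
        [centre[0] + radius * np.cos(a), centre[1] + radius * np.sin(a)], axis=-1
    )
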