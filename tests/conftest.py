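import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from colloidjump import table1_field
from colloidjump.synthetic import SynthConfig, generate_channel_trajectories

settings.register_profile(
    "suite", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table1():
    """Fitted activity field of the 100 um-wide channel (packaged config)."""
    return table1_field()


@pytest.fixture(scope="session")
def channel_dataset(table1):
    """Shared synthetic dataset at study scale: 120 tracks x 600 s at 10 fps.

    ~20k labelled jump events, comparable to an experimental campaign's
    event count; reused by detection, fitting and acceptance tests.
    """
    cfg = SynthConfig(
        geometry=table1.geometry,
        field=table1,
        n_particles=120,
        n_frames=6000,
        seed=20_260_925,
    )
    return cfg, generate_channel_trajectories(cfg)
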