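"""Shared fixtures: one radar geometry, one subject, cached echoes."""

import pytest
from hypothesis import HealthCheck, settings

from ssavmd import ChestMotion, RadarConfig, Scene, synthesize_echo
from ssavmd.echo_sim import study_scene

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def radar():
    return RadarConfig()


@pytest.fixture(scope="session")
def motion():
    return ChestMotion(d0=0.6, fr=0.25, fh=1.4)


@pytest.fixture(scope="session")
def noiseless_chest(radar, motion):
    """Chest return only: no clutter, no DC, no noise."""
    return synthesize_echo(radar, Scene(av=1.0), motion, seed=None)


@pytest.fixture(scope="session")
def study_echo(radar, motion):
    """Standard 0 dB study environment, fixed noise seed."""
    scene = study_scene(radar, motion)
    return synthesize_echo(radar, scene, motion, seed=123), scene
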