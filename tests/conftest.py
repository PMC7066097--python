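import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ramus import (
    HeadModel,
    build_source_space,
    eeg_leadfield,
    magnetometers_from_electrodes,
    meg_radial_leadfield,
    upper_hemisphere_sensors,
)


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def head_homogeneous():
    # all conductivities equal: the layered series must match the
    # single-sphere closed form
    return HeadModel(conductivities=(0.33, 0.33, 0.33), series_truncation=200,
                     series_tol=1e-12)


@pytest.fixture(scope="session")
def electrodes():
    return upper_hemisphere_sensors(40, radius_mm=100.0)


@pytest.fixture(scope="session")
def magnetometers(electrodes):
    return magnetometers_from_electrodes(electrodes)


@pytest.fixture(scope="session")
def space_small(head):
    return build_source_space(120, 0.0, 80.0, seed=3, head=head)


@pytest.fixture(scope="session")
def eeg_small(space_small, electrodes, head):
    return eeg_leadfield(space_small, electrodes, head)


@pytest.fixture(scope="session")
def meg_small(space_small, magnetometers, head):
    return meg_radial_leadfield(space_small, magnetometers, head)
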