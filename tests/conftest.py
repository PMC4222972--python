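import numpy as np
import pytest
from hypothesis import settings

import bandloc as bl

settings.register_profile("default", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sensors32() -> bl.SensorArray:
    return bl.geodesic_sensors(32)


@pytest.fixture(scope="session")
def patches20() -> bl.CorticalPatchModel:
    """20-patch toy source space spanning depths 30-60 mm."""
    return bl.synthetic_patch_model(10, seed=2, radius_range=(30.0, 60.0))


@pytest.fixture(scope="session")
def toy_lead_field(sensors32, patches20) -> bl.LeadField:
    return bl.build_spherical_lead_field(sensors32, patches20)


@pytest.fixture(scope="session")
def toy_lead_field_car(toy_lead_field) -> bl.LeadField:
    return bl.apply_common_average(toy_lead_field)


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    return bl.make_fixture_suite(out, seed=7)


def separated_patch_line(n: int = 5, spacing: float = 40.0) -> bl.CorticalPatchModel:
    """Patches on a widely spaced line, for exact-recovery BOLD tests."""
    centers = np.zeros((n, 3))
    centers[:, 0] = (np.arange(n) - (n - 1) / 2.0) * spacing
    orient = np.tile([0.0, 0.0, 1.0], (n, 1))
    hemi = np.where(centers[:, 0] < 0, "L", "R")
    return bl.CorticalPatchModel(centers, orient, hemi)
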