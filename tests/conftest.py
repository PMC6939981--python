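import numpy as np
import pytest

from tiltcal import (
    ProjectionGeometry,
    build_calibration_table,
    generate_cohort,
    template_landmarks,
)


@pytest.fixture(scope="session")
def male_template():
    return template_landmarks("male")


@pytest.fixture(scope="session")
def female_template():
    return template_landmarks("female")


@pytest.fixture(scope="session")
def parallel_geom():
    return ProjectionGeometry.parallel()


@pytest.fixture(scope="session")
def default_geom():
    return ProjectionGeometry()


@pytest.fixture(scope="session")
def small_cohort():
    """5 male + 5 female pelvises at the default variation level."""
    return generate_cohort(5, 5, seed=1)


@pytest.fixture(scope="session")
def small_calibration_table(small_cohort):
    """Noiseless default sweep for the 10-subject cohort (130 rows)."""
    return build_calibration_table(small_cohort)


def rigid_distances(lm):
    pts = lm.all_coordinates()
    return np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
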