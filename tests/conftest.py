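import pytest

from pigplanim.postures import packaged_study_tables
from pigplanim.scene import CameraModel, fit_shape_coefficient


@pytest.fixture(scope="session")
def tables():
    return packaged_study_tables()


@pytest.fixture(scope="session")
def tables_by_code(tables):
    return {r.posture: r for r in tables}


@pytest.fixture(scope="session")
def coefficients(tables):
    return fit_shape_coefficient(tables)


@pytest.fixture(scope="session")
def camera():
    return CameraModel(image_width=1600, image_height=1100, floor_scale=500.0)
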