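import warnings

import pytest
from hypothesis import HealthCheck, settings

from vitd_rct import DoseResponseCurve, StatusResponseModel
from vitd_rct.status_response import CalibrationWarning

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_curve() -> DoseResponseCurve:
    return DoseResponseCurve()


@pytest.fixture(scope="session")
def calibration_model() -> StatusResponseModel:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CalibrationWarning)
        return StatusResponseModel()


@pytest.fixture(scope="session")
def parametric_model() -> StatusResponseModel:
    return StatusResponseModel(StatusResponseModel.PARAMETRIC)
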