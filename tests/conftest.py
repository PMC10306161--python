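import pytest

from ngsbia import default_parameters, calibrate_basecase, run_analysis


@pytest.fixture()
def base():
    return default_parameters()


@pytest.fixture(scope="session")
def calibrated():
    """Base case after the calibration ladder (shared; treat as read-only)."""
    p, report = calibrate_basecase(default_parameters())
    return p, report


@pytest.fixture(scope="session")
def calibrated_results(calibrated):
    p, _ = calibrated
    return run_analysis(p)
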