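import pytest

from ocuflow import BaselinePhysiology, DrugRegimen, calibrate


@pytest.fixture(scope="session")
def baseline():
    return BaselinePhysiology()


@pytest.fixture(scope="session")
def regimen():
    return DrugRegimen()


@pytest.fixture(scope="session")
def model():
    """Default calibration with the nonlinear pressure route (kappa_hyd = 0.99)."""
    return calibrate()


@pytest.fixture(scope="session")
def model_linear(model):
    """Same calibration with the pressure route reduced to a linear resistor."""
    return model.with_kappa(kappa_hyd=0.0)


@pytest.fixture(scope="session")
def model_strong(model):
    """Strongly nonlinear pressure route (kappa_hyd = 10)."""
    return model.with_kappa(kappa_hyd=10.0)
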