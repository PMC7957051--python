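import pytest

from mmcea import ParameterSet, calibrated_pipeline, default_schedules, make_life_table


@pytest.fixture(scope="session")
def lifetable():
    return make_life_table()


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


@pytest.fixture(scope="session")
def schedules():
    return default_schedules()


@pytest.fixture(scope="session")
def calibrated():
    """Base-case pipeline calibrated to the published per-arm LY/QALY values."""
    pipe, cal = calibrated_pipeline()
    return pipe, cal
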