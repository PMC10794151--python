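import pytest

from navclamp.calibrate import default_params, measure_pipeline


@pytest.fixture(scope="session")
def params():
    """The calibrated default gating model (computed once per session)."""
    return default_params()


@pytest.fixture(scope="session")
def pipeline(params):
    """Noise-free full-pipeline measurement of the calibrated defaults."""
    return measure_pipeline(params)
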