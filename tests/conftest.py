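import pytest

from ecmodelkit import ToyGemSpec, build_toy_pipeline


@pytest.fixture(scope="session")
def toy():
    """Default toy fixture, full pipeline, seed 0."""
    return build_toy_pipeline(ToyGemSpec(seed=0))


@pytest.fixture(scope="session")
def toy_calib():
    """Calibration fixture: respiration kcat under-valued 10x."""
    return build_toy_pipeline(ToyGemSpec(seed=0, undervalue_resp_kcat=True))
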