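import pytest

from coagsim import load_model
from coagsim.assays import run_aptt, run_pt


@pytest.fixture(scope="session")
def model():
    return load_model()


@pytest.fixture(scope="session")
def pt_control(model):
    return run_pt(model).clotting_time


@pytest.fixture(scope="session")
def aptt_control(model):
    return run_aptt(model).clotting_time
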