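import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "fixed",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")

import emfkit as ek


@pytest.fixture(scope="session")
def tiny_data():
    return ek.gen_fixture("tiny")


@pytest.fixture(scope="session")
def paper_data():
    return ek.gen_fixture("paper_shape")
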