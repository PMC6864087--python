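import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_lib():
    from bpaprof import load_reference_library

    return load_reference_library()


@pytest.fixture(scope="session")
def pp1_graph(reference_lib):
    return reference_lib.compound("PP1").graph()
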