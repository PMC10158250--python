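import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design7():
    """The SsInS flanks around a 7-nt N-region (the screen's design)."""
    from tfy1h.library_model import design_template

    return design_template(7)
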