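import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def gr2e():
    """The preset synthetic event bundle (published geometry, seed 1)."""
    from eventscreen.synth import gr2e_bundle

    return gr2e_bundle(1)


@pytest.fixture(scope="session")
def gr2e_geometry(gr2e):
    """Geometry recovered from the preset bundle by exact anchoring."""
    from eventscreen.junction import characterize_borders

    return characterize_borders(gr2e.host, gr2e.tdna, gr2e.event)
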