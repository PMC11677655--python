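import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    """Packaged property table of the ten headspace-relevant compounds."""
    from nanoaroma import load_oil_properties

    return load_oil_properties()


@pytest.fixture(scope="session")
def composition():
    """Packaged 31-compound GC-MS composition of the essential oil."""
    from nanoaroma import load_oil_composition

    return load_oil_composition()
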