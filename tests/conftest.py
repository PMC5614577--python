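import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_nest_paths(tmp_path_factory):
    """Seeded incursion-style nest dataset written once per session."""
    from colonykin import make_fixture_nest

    out = tmp_path_factory.mktemp("fixture_nest")
    return make_fixture_nest(out, seed=20160916)
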