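import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_db():
    """Small deterministic database shared by screening tests."""
    from allerscreen.fixtures import FixtureSpec, make_db

    return make_db(FixtureSpec(seed=101, n_entries=10, length_range=(90, 200)))
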