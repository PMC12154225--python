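import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def corpuscle_default():
    """Default three-shell corpuscle phantom, shared across morphometry tests."""
    from pacinia.synthetic import PhantomSpec, make_corpuscle_phantom

    return make_corpuscle_phantom(PhantomSpec())
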