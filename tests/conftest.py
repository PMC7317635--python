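import pytest
from hypothesis import HealthCheck, settings

from pamslt import InterventionSpec, generate_inputs, prepare_bundle

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_inputs():
    """Synthetic inputs under the default scenario (seed 0)."""
    return generate_inputs()


@pytest.fixture(scope="session")
def bundle(default_inputs):
    """Prepared model bundle with cached BAU for the default scenario."""
    return prepare_bundle(default_inputs)


@pytest.fixture(scope="session")
def base_result(bundle):
    """Base-case cost-effectiveness result (central parameters, 3% discount)."""
    return bundle.run(InterventionSpec())
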