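import pytest
from hypothesis import HealthCheck, settings

from nanofix.pipeline import run_bundle
from nanofix.synthetic_data import SynthConfig, generate

settings.register_profile(
    "nanofix",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("nanofix")


@pytest.fixture(scope="session")
def default_bundle():
    """The noise-free default synthetic bundle (5 sites, ~2,000 sequences)."""
    return generate(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def default_result(default_bundle):
    bundle, _ = default_bundle
    return run_bundle(bundle)
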