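import pytest

from fetaldose import default_pregnant_phantom, generate_coefficients
from fetaldose.coefficients import SynthCoeffParams


@pytest.fixture(scope="session")
def phantom():
    return default_pregnant_phantom()


@pytest.fixture(scope="session")
def coeffs(phantom):
    """Jitter-free synthetic coefficients (exact closed forms)."""
    return generate_coefficients(phantom, SynthCoeffParams(jitter=0.0, seed=0))


@pytest.fixture(scope="session")
def coeffs_jittered(phantom):
    return generate_coefficients(phantom, SynthCoeffParams(jitter=0.1, seed=7))
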