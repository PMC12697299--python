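import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mcfnano import CurveSpec, ImageSpec, ProbeParams

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def probe() -> ProbeParams:
    return ProbeParams()


@pytest.fixture(scope="session")
def fast_curve_spec() -> CurveSpec:
    """Shorter ramps keep unit tests quick; physics is unchanged."""
    return CurveSpec(n_samples=2000)


@pytest.fixture(scope="session")
def small_image_spec() -> ImageSpec:
    return ImageSpec(n_pixels=256, scan_size_nm=2500.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
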